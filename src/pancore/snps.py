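"""Consensus sequences, SNP statistics and clade-specific ecoSNP calls.

Two SNP tallies are reported side by side because published totals are
ambiguous between them: the per-strain mismatch sum against the
consensus ("sum SNP") and the count of variable columns.  Clade
analyses use columns.  Gaps never enter state counts, and a column with
any gapped strain is never an ecoSNP.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .phylo import MSA

_GAP = "-"
_ORDER = "ACGT"  # alphabetical; consensus ties resolve to the earlier base


@dataclass
class ConsensusProfile:
    consensus: str
    counts: pd.DataFrame  # columns A/C/G/T, one row per alignment column

    @property
    def length(self) -> int:
        return len(self.consensus)


@dataclass
class SNPReport:
    gene: str | None
    per_strain: dict[str, int]
    variable_positions: int
    polyvariable_positions: int
    sum_snp: int
    length: int

    @property
    def snp_per_kb(self) -> float:
        """Variable-column density."""
        return self.variable_positions / (self.length / 1000.0)

    @property
    def sum_snp_per_kb(self) -> float:
        return self.sum_snp / (self.length / 1000.0)


@dataclass(frozen=True)
class EcoSnpCall:
    gene: str
    column: int
    base_by_clade: tuple[tuple[str, str], ...]


@dataclass
class EcoSNPReport:
    calls: list[EcoSnpCall]

    def as_tuples(self) -> set[tuple]:
        return {(c.gene, c.column, c.base_by_clade) for c in self.calls}


def _msa_array(msa: MSA) -> np.ndarray:
    return np.array([list(r) for r in msa.rows], dtype="U1")


def build_consensus(msa: MSA) -> ConsensusProfile:
    """Majority base per column; ties alphabetical; all-gap columns -> N."""
    if not msa.rows:
        raise ValueError("empty MSA")
    arr = _msa_array(msa)
    counts = np.stack([(arr == b).sum(axis=0) for b in _ORDER], axis=1)
    consensus = []
    for col in range(arr.shape[1]):
        c = counts[col]
        if c.sum() == 0:
            consensus.append("N")
        else:
            consensus.append(_ORDER[int(np.argmax(c))])  # argmax = first max
    df = pd.DataFrame(counts, columns=list(_ORDER))
    return ConsensusProfile("".join(consensus), df)


def call_snps(msa: MSA, consensus: ConsensusProfile,
              gene: str | None = None) -> SNPReport:
    """Per-strain mismatches vs consensus plus column variability tallies."""
    if consensus.length != msa.length:
        raise ValueError("consensus length does not match MSA")
    arr = _msa_array(msa)
    cons = np.array(list(consensus.consensus), dtype="U1")
    ungapped = arr != _GAP
    mismatch = (arr != cons[None, :]) & ungapped
    per_strain = {name: int(m.sum()) for name, m in zip(msa.names, mismatch)}
    n_states = np.zeros(msa.length, dtype=int)
    for b in _ORDER:
        n_states += (arr == b).any(axis=0)
    variable = int((n_states >= 2).sum())
    poly = int((n_states >= 3).sum())
    return SNPReport(
        gene=gene or msa.cluster_id,
        per_strain=per_strain,
        variable_positions=variable,
        polyvariable_positions=poly,
        sum_snp=int(mismatch.sum()),
        length=msa.length,
    )


def detect_ecosnps(msa: MSA, clades: dict[str, str],
                   gene: str | None = None) -> list[EcoSnpCall]:
    """Columns that perfectly partition strains by clade.

    A column qualifies iff every strain is ungapped there, exactly two
    states occur, and every clade is monomorphic (so the two states are
    a union-of-clades split).  With two clades this is exactly the
    two-state/clade-partition rule.
    """
    missing = [n for n in msa.names if n not in clades]
    if missing:
        raise ValueError(f"strains without clade label: {missing}")
    clade_labels = sorted(set(clades[n] for n in msa.names))
    if len(clade_labels) < 2:
        raise ValueError("need >= 2 clades")
    for clade in clade_labels:
        if sum(1 for n in msa.names if clades[n] == clade) < 2:
            raise ValueError(f"clade {clade} has fewer than 2 strains")
    arr = _msa_array(msa)
    rows_by_clade = {
        clade: np.array([i for i, n in enumerate(msa.names)
                         if clades[n] == clade])
        for clade in clade_labels
    }
    calls = []
    for col in range(msa.length):
        column = arr[:, col]
        if (column == _GAP).any():
            continue
        states = set(column.tolist())
        if len(states) != 2:
            continue
        base_by_clade = {}
        ok = True
        for clade, rows in rows_by_clade.items():
            vals = set(column[rows].tolist())
            if len(vals) != 1:
                ok = False
                break
            base_by_clade[clade] = next(iter(vals))
        if ok and len(set(base_by_clade.values())) == 2:
            calls.append(EcoSnpCall(gene or msa.cluster_id or "",
                                    col, tuple(sorted(base_by_clade.items()))))
    return calls


def detect_ecosnps_many(msas: dict[str, MSA],
                        clades: dict[str, str]) -> EcoSNPReport:
    calls: list[EcoSnpCall] = []
    for fam in sorted(msas):
        calls.extend(detect_ecosnps(msas[fam], clades, gene=fam))
    return EcoSNPReport(calls)


def snp_report_frame(reports: list[SNPReport]) -> pd.DataFrame:
    """One row per gene, mirroring the published supplementary layout."""
    rows = []
    for rep in reports:
        rows.append({
            "gene": rep.gene,
            "sum_snp": rep.sum_snp,
            "snp_per_base": rep.sum_snp / rep.length,
            "variable_positions": rep.variable_positions,
            "polyvariable_positions": rep.polyvariable_positions,
            "length_bp": rep.length,
            "variable_per_kb": rep.snp_per_kb,
        })
    return pd.DataFrame(rows).set_index("gene")


def write_snp_report_tsv(reports: list[SNPReport], path) -> Path:
    path = Path(path)
    snp_report_frame(reports).to_csv(path, sep="\t", index_label="gene")
    return path


def write_ecosnp_tsv(report: EcoSNPReport, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("gene\tcolumn\tclade\tbase\n")
        for call in report.calls:
            for clade, base in call.base_by_clade:
                fh.write(f"{call.gene}\t{call.column}\t{clade}\t{base}\n")
    return path
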