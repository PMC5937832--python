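"""Core-vs-pan functional category fold increases with Fisher's exact test.

Annotation arrives as a two-column gene->category table (many-to-many
allowed).  For each category the 2x2 table is
[[category-in-core, other-core], [category-in-pan, other-pan]]; the
two-sided p-value sums all hypergeometric tables with fixed margins
whose probability does not exceed the observed table's.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

P_FLAG = 0.01


@dataclass(frozen=True)
class CategoryCounts:
    category: str
    core: int
    softcore: int
    pan: int

    def __post_init__(self):
        if min(self.core, self.softcore, self.pan) < 0:
            raise ValueError("counts must be non-negative")


def fisher_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    Stable log-space hypergeometric enumeration; probabilities equal to
    the observed one (up to a tiny relative slack) are included.
    """
    for x in (a, b, c, d):
        if not isinstance(x, (int, np.integer)):
            raise ValueError("table entries must be integers")
        if x < 0:
            raise ValueError("table entries must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise ValueError("at least one margin must be positive")
    row1, col1 = a + b, a + c
    k = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    logp = hypergeom.logpmf(k, n, col1, row1)
    log_obs = hypergeom.logpmf(a, n, col1, row1)
    include = logp <= log_obs + 1e-9
    return float(min(1.0, np.exp(logp[include]).sum()))


def _round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def fold_increase_table(counts: list[CategoryCounts],
                        core_total: int | None = None,
                        softcore_total: int | None = None,
                        pan_total: int | None = None) -> pd.DataFrame:
    """Per-category fold increases (one decimal, half-up) and Fisher p.

    Totals default to the column sums over the supplied categories.
    Categories with a zero core (or softcore) count get an undefined
    fold, flagged as NaN.
    """
    if not counts:
        raise ValueError("no categories")
    core_total = core_total if core_total is not None else sum(c.core for c in counts)
    softcore_total = (softcore_total if softcore_total is not None
                      else sum(c.softcore for c in counts))
    pan_total = pan_total if pan_total is not None else sum(c.pan for c in counts)
    if min(core_total, softcore_total, pan_total) <= 0:
        raise ValueError("set totals must be positive")
    rows = []
    for cc in counts:
        if cc.core > core_total or cc.pan > pan_total:
            raise ValueError(f"{cc.category}: count exceeds set total")
        fold_cp = (_round_half_up(cc.pan / cc.core) if cc.core else np.nan)
        fold_sp = (_round_half_up(cc.pan / cc.softcore) if cc.softcore else np.nan)
        p = fisher_exact(cc.core, core_total - cc.core,
                         cc.pan, pan_total - cc.pan)
        rows.append({
            "category": cc.category,
            "core": cc.core, "softcore": cc.softcore, "pan": cc.pan,
            "fold_core_pan": fold_cp,
            "fold_softcore_pan": fold_sp,
            "p_value": p,
            "significant": p < P_FLAG,
        })
    return pd.DataFrame(rows).set_index("category")


def read_annotation_tsv(path) -> dict[str, list[str]]:
    """gene -> categories from a two-column TSV (many-to-many allowed)."""
    mapping: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed annotation line {line!r}")
            mapping.setdefault(fields[0], []).append(fields[1])
    return mapping


def category_counts_from_annotation(
    annotation: dict[str, list[str]],
    core_genes: set[str], softcore_genes: set[str], pan_genes: set[str],
) -> list[CategoryCounts]:
    """Tally annotated genes per category for each gene set."""
    categories = sorted({cat for cats in annotation.values() for cat in cats})
    out = []
    for cat in categories:
        genes = {g for g, cats in annotation.items() if cat in cats}
        out.append(CategoryCounts(
            cat,
            core=len(genes & core_genes),
            softcore=len(genes & softcore_genes),
            pan=len(genes & pan_genes),
        ))
    return out


def write_enrichment_tsv(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index_label="category")
    return path
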