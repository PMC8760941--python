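"""Selection-intensity post-processing.

Branch-model tests (e.g. HyPhy RELAX) produce, per ortholog cluster, a
selection-intensity parameter k for the parasite branches relative to host
branches, a likelihood-ratio p-value, and the largest per-branch dN/dS.
This module ingests those records, applies the standard quality filter
(clusters with any dN/dS > 10 are excluded), controls the FDR over the
retained tests, flags relaxed (k < 1) and intensified (k > 1) clusters, and
compares k between clusters with different degrees of parasite loss with a
Wilcoxon rank-sum test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .convstats import bh_adjust
from .gainloss import CallTable

OMEGA_EXCLUSION = 10.0  # max per-branch dN/dS beyond which the fit is untrustworthy


@dataclass
class SelectionRecord:
    cluster_id: str
    k: float
    p_lrt: float
    max_omega: float
    excluded: bool
    fdr: float | None = None


def load_selection_records(path) -> list[SelectionRecord]:
    """Read a selection-results TSV (cluster_id, k, p_lrt, max_omega).

    Records with ``max_omega`` > 10 are flagged excluded and left out of the
    FDR pool; FDR values are Benjamini-Hochberg over the remaining LRT
    p-values.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"cluster_id", "k", "p_lrt", "max_omega"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"selection TSV lacks columns: {sorted(missing)}")
    if (df["k"] < 0).any():
        bad = df.loc[df["k"] < 0, "cluster_id"].tolist()
        raise ValueError(f"negative selection intensity k for clusters: {bad}")
    records = [
        SelectionRecord(
            cluster_id=str(r.cluster_id),
            k=float(r.k),
            p_lrt=float(r.p_lrt),
            max_omega=float(r.max_omega),
            excluded=float(r.max_omega) > OMEGA_EXCLUSION,
        )
        for r in df.itertuples()
    ]
    kept = [r for r in records if not r.excluded]
    for r, q in zip(kept, bh_adjust([r.p_lrt for r in kept])):
        r.fdr = q
    return records


def flag_convergent_relaxation(
    records: list[SelectionRecord], fdr_threshold: float = 0.05
) -> dict:
    """Flag significantly relaxed (k < 1) and intensified (k > 1) clusters."""
    relaxed, intensified = [], []
    for r in records:
        if r.excluded or r.fdr is None or r.fdr >= fdr_threshold:
            continue
        if r.k < 1.0:
            relaxed.append(r.cluster_id)
        elif r.k > 1.0:
            intensified.append(r.cluster_id)
    return {
        "relaxed": sorted(relaxed),
        "intensified": sorted(intensified),
        "n_relaxed": len(relaxed),
        "n_intensified": len(intensified),
    }


def classify_loss_category(table: CallTable) -> dict[str, str]:
    """Bucket clusters by how many parasite lineages lost orthologs."""
    counts = table.calls.groupby("cluster_id", sort=False)["parasite_loss"].sum()
    out = {}
    for cid, c in counts.items():
        out[cid] = "none" if c == 0 else ("one" if c == 1 else "multiple")
    return out


@dataclass(frozen=True)
class WilcoxonResult:
    W: float
    p_value: float
    n1: int
    n2: int
    method: str


def wilcoxon_rank_sum(a, b, exact_limit: int = 10_000) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test with midranks.

    W is the Mann-Whitney U of the first group (its rank sum minus the
    minimum possible), so 0 <= W <= n1*n2.  The p-value is exact
    (permutation enumeration) when there are no ties and n1*n2 is small,
    otherwise a normal approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    use_exact = (not ties) and a.size * b.size <= exact_limit
    res = stats.mannwhitneyu(
        a, b,
        alternative="two-sided",
        method="exact" if use_exact else "asymptotic",
        use_continuity=True,
    )
    return WilcoxonResult(
        W=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n1=int(a.size),
        n2=int(b.size),
        method="exact" if use_exact else "normal",
    )


def loss_category_report(
    table: CallTable, records: list[SelectionRecord]
) -> pd.DataFrame:
    """Compare selection intensity k across parasite-loss categories.

    Runs the none-vs-one and none-vs-multiple Wilcoxon comparisons on
    non-excluded records, mirroring the standard presentation of relaxed
    selection preceding loss.
    """
    cat = classify_loss_category(table)
    k_by_cat: dict[str, list[float]] = {"none": [], "one": [], "multiple": []}
    for r in records:
        if r.excluded or r.cluster_id not in cat:
            continue
        k_by_cat[cat[r.cluster_id]].append(r.k)
    rows = []
    for g1, g2 in itertools.combinations(("none", "one", "multiple"), 2):
        if not k_by_cat[g1] or not k_by_cat[g2]:
            continue
        res = wilcoxon_rank_sum(k_by_cat[g1], k_by_cat[g2])
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "n1": res.n1,
                "n2": res.n2,
                "W": res.W,
                "p_value": res.p_value,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)
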