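"""Convergence statistics.

The central test asks whether losses (or gains) of the same ortholog
cluster across independent parasite lineages co-occur more often than
independence predicts.  Per species, the marginal loss probability is the
fraction of clusters with loss; the null probability of convergent loss is
the product of the three parasite (or host) marginals; the observed
probability x/n is compared with that null by a two-sided exact binomial
test, with a Clopper-Pearson interval on x/n and an exact rejection-region
power computation.  Enrichment of convergent loss within ancestral
subfamilies reuses the family-wide null with Benjamini-Hochberg adjustment
across subfamilies.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gainloss import CallTable


def marginal_loss_prob(table: CallTable, species: str) -> float:
    """Fraction of ortholog clusters in which ``species`` lost orthologs."""
    if table.n == 0:
        raise ZeroDivisionError("no clusters: marginal undefined")
    return table.loss_count(species) / table.n


def marginal_gain_prob(table: CallTable, species: str) -> float:
    if table.n == 0:
        raise ZeroDivisionError("no clusters: marginal undefined")
    return table.gain_count(species) / table.n


def expected_convergent_prob(marginals) -> float:
    """Null probability of simultaneous independent events: the product."""
    p = 1.0
    for m in marginals:
        if not 0.0 <= m <= 1.0:
            raise ValueError(f"marginal {m} outside [0, 1]")
        p *= m
    return p


def binom_test_two_sided(x: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p-value, point-probability convention.

    Sums Binom(j; n, p0) over every outcome j whose point probability does
    not exceed that of x by more than a relative tolerance of 1e-7 -- the
    convention of R's ``binom.test`` (scipy's ``binomtest`` implements the
    same rule and is used here).
    """
    if not (isinstance(x, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise ValueError("x and n must be integers")
    if not 0 <= x <= n:
        raise ValueError(f"x={x} outside 0..n={n}")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0={p0} outside [0, 1]")
    if p0 == 0.0:
        return 1.0 if x == 0 else 0.0
    if p0 == 1.0:
        return 1.0 if x == n else 0.0
    return float(stats.binomtest(int(x), int(n), p0).pvalue)


def clopper_pearson(x: int, n: int, conf_level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for x/n."""
    if not 0 <= x <= n:
        raise ValueError(f"x={x} outside 0..n={n}")
    alpha = 1.0 - conf_level
    low = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return low, high


def binom_power(
    n: int,
    p0: float,
    p1: float,
    alpha: float = 0.05,
    method: str = "exact",
    B: int = 100_000,
    seed: int | None = None,
) -> float:
    """Power of the two-sided exact binomial test against alternative p1.

    ``exact`` enumerates the rejection region R = {j : p(j; n, p0) <= alpha}
    and sums Binom(j; n, p1) over it; ``simulate`` draws B binomial samples
    under p1 and reports the rejection fraction.
    """
    reject = np.array(
        [binom_test_two_sided(j, n, p0) <= alpha for j in range(n + 1)]
    )
    if method == "exact":
        pmf = stats.binom.pmf(np.arange(n + 1), n, p1)
        return float(pmf[reject].sum())
    if method == "simulate":
        if B < 10_000:
            raise ValueError("simulation requires B >= 10000")
        rng = np.random.default_rng(seed)
        draws = rng.binomial(n, p1, size=B)
        return float(reject[draws].mean())
    raise ValueError(f"unknown power method {method!r}")


@dataclass(frozen=True)
class ConvergenceTestResult:
    side: str
    event: str
    x: int
    n: int
    marginals: dict[str, float]
    p0: float
    p_obs: float
    ci: tuple[float, float]
    p_value: float
    power: float | None
    power_method: str | None
    alpha: float
    conf_level: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ci"] = list(self.ci)
        return d


def convergence_test(
    table: CallTable,
    side: str = "parasite",
    event: str = "loss",
    alpha: float = 0.05,
    conf_level: float = 0.95,
    power_method: str | None = "exact",
    seed: int | None = None,
) -> ConvergenceTestResult:
    """Test for convergent loss (or gain) across all lineages of one side."""
    species = table.config.parasites if side == "parasite" else table.config.hosts
    if event == "loss":
        marginals = {sp: marginal_loss_prob(table, sp) for sp in species}
    elif event == "gain":
        marginals = {sp: marginal_gain_prob(table, sp) for sp in species}
    else:
        raise ValueError(f"unknown event {event!r}")
    n = table.n
    x = table.convergent_count(side, event)
    p0 = expected_convergent_prob(marginals.values())
    p_obs = x / n
    power = None
    if power_method is not None:
        power = binom_power(n, p0, p_obs, alpha=alpha, method=power_method, seed=seed)
    return ConvergenceTestResult(
        side=side,
        event=event,
        x=x,
        n=n,
        marginals=marginals,
        p0=p0,
        p_obs=p_obs,
        ci=clopper_pearson(x, n, conf_level),
        p_value=binom_test_two_sided(x, n, p0),
        power=power,
        power_method=power_method,
        alpha=alpha,
        conf_level=conf_level,
    )


def bh_adjust(pvalues) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    pvalues = list(pvalues)
    if not pvalues:
        return []
    if any(not 0.0 <= p <= 1.0 for p in pvalues):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(pvalues, method="fdr_bh")[1])


@dataclass(frozen=True)
class EnrichmentRow:
    subfamily: str
    x: int
    n: int
    p_obs: float
    ci: tuple[float, float]
    p_raw: float
    p_adj: float


def subfamily_enrichment(
    table: CallTable,
    subfamilies: dict[str, str | None],
    p0: float | None = None,
    side: str = "parasite",
    event: str = "loss",
    conf_level: float = 0.95,
) -> list[EnrichmentRow]:
    """Per-subfamily convergent-event enrichment against a shared null.

    ``subfamilies`` maps cluster ids to subfamily labels (``None`` =
    unassigned, excluded).  ``p0`` defaults to the family-wide expected
    convergent probability from :func:`convergence_test`.  Raw p-values are
    two-sided exact binomial; adjustment is Benjamini-Hochberg across all
    tested subfamilies, rows sorted by adjusted p.
    """
    if p0 is None:
        p0 = convergence_test(table, side, event, power_method=None).p0
    convergent = set(table.convergent_clusters(side, event))
    groups: dict[str, list[str]] = {}
    for cid, sf in subfamilies.items():
        if sf is not None:
            groups.setdefault(sf, []).append(cid)
    rows = []
    for sf in sorted(groups):
        cids = groups[sf]
        n_s = len(cids)
        if n_s == 0:
            continue
        x_s = sum(c in convergent for c in cids)
        rows.append(
            (sf, x_s, n_s, x_s / n_s, clopper_pearson(x_s, n_s, conf_level),
             binom_test_two_sided(x_s, n_s, p0))
        )
    adj = bh_adjust([r[5] for r in rows])
    out = [
        EnrichmentRow(subfamily=sf, x=x, n=n, p_obs=pobs, ci=ci, p_raw=praw, p_adj=padj)
        for (sf, x, n, pobs, ci, praw), padj in zip(rows, adj)
    ]
    return sorted(out, key=lambda r: (r.p_adj, r.p_raw, r.subfamily))


@dataclass(frozen=True)
class PropTestResult:
    statistic: float
    df: int
    p_value: float


def prop_test(successes, totals, correction: bool = True) -> PropTestResult:
    """Pearson chi-square test for equality of k proportions.

    Built on the 2 x k success/failure contingency table; the Yates
    continuity correction is applied only in the two-group case, matching
    the usual convention.
    """
    successes = [int(s) for s in successes]
    totals = [int(t) for t in totals]
    if len(successes) != len(totals) or len(successes) < 2:
        raise ValueError("need k >= 2 equal-length success/total lists")
    if any(t <= 0 for t in totals):
        raise ValueError("all totals must be positive")
    if any(s < 0 or s > t for s, t in zip(successes, totals)):
        raise ValueError("successes must lie in 0..total")
    tbl = np.array([successes, [t - s for s, t in zip(successes, totals)]])
    use_corr = correction and len(successes) == 2
    chi2, p, dof, _ = stats.chi2_contingency(tbl, correction=use_corr)
    return PropTestResult(statistic=float(chi2), df=int(dof), p_value=float(p))
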