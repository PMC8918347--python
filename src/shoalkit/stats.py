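"""Nonparametric group comparisons.

The analysis chain for comparing genotype / age / rearing groups:
a Kolmogorov-Smirnov normality screen (which motivates rank tests for this
kind of behavioral data), a Kruskal-Wallis omnibus test per stratum,
followed by post-hoc pairwise Mann-Whitney-U (Wilcoxon rank-sum) tests
with optional Benjamini-Hochberg adjustment per post-hoc family.

All tests are two-sided. Rank tests use mid-ranks with tie-corrected
variance; the rank-sum test enumerates the exact null distribution for
small tie-free samples. Significance stars follow the usual thresholds
(* p<0.05, ** p<0.01, *** p<0.001).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, UndefinedStatisticError

EXACT_TOTAL_N = 25  # largest tie-free total sample enumerated exactly
EXACT_KW_TOTAL_N = 10  # largest total for exact Kruskal-Wallis permutation


@dataclass
class GroupSample:
    """Observations for one group (e.g. one genotype x age x rearing cell).

    ``label`` maps factor names to levels, e.g.
    ``{"genotype": "oxtr-/-", "age_wpf": 4, "rearing": "social"}``.
    """

    label: Mapping[str, object]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ConfigurationError("GroupSample needs a 1-D, non-empty value array")
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("GroupSample values must be finite")
        self.label = dict(self.label)

    @property
    def n(self) -> int:
        return self.values.size

    def name(self) -> str:
        return "/".join(str(v) for v in self.label.values())


@dataclass(frozen=True)
class ComparisonDesign:
    """One post-hoc family: pairwise-compare the levels of ``compare``
    within every combination of the ``within`` factors (mirroring e.g.
    age-within-genotype or genotype-within-age comparisons)."""

    compare: str
    within: tuple[str, ...] = ()
    name: str | None = None

    @property
    def family(self) -> str:
        return self.name or (
            f"{self.compare}_within_{'_'.join(self.within)}" if self.within else self.compare
        )


@dataclass
class GroupComparison:
    """Omnibus + post-hoc results for one stratum of one family."""

    family: str
    stratum: dict
    omnibus_h: float
    omnibus_p: float
    pairwise: pd.DataFrame  # group_a, group_b, statistic, p_raw, p_adj, stars
    adjustment: str


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def ks_normality(values: Sequence[float]) -> float:
    """One-sample Kolmogorov-Smirnov test against a normal distribution
    with the sample's own mean and SD; returns the p-value.

    Note the usual caveat: estimating the parameters from the sample makes
    the classical KS p-value anti-conservative (the Lilliefors correction
    would be stricter); this mirrors the common `kstest`-style screen.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ConfigurationError("normality screen needs n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        raise UndefinedStatisticError("constant sample: normality test undefined")
    return float(sps.kstest(x, "norm", args=(x.mean(), sd)).pvalue)


def _kw_h(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H statistic."""
    all_vals = np.concatenate(groups)
    n = all_vals.size
    ranks = sps.rankdata(all_vals)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(all_vals, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    if tie == 0:
        return 0.0
    return h / tie


def kruskal_wallis(groups: Sequence[GroupSample | Sequence[float]],
                   method: str = "auto") -> tuple[float, float]:
    """Kruskal-Wallis omnibus test across >= 2 groups; returns (H, p).

    ``method``: ``"chi2"`` for the chi-square approximation (g-1 df),
    ``"exact"`` for full permutation enumeration (total n <= 10), or
    ``"auto"`` (exact for tiny totals, chi-square otherwise). All values
    identical gives H = 0, p = 1.
    """
    arrs = [np.asarray(g.values if isinstance(g, GroupSample) else g, dtype=float)
            for g in groups]
    if len(arrs) < 2:
        raise ConfigurationError("need at least 2 groups")
    if any(a.size < 1 for a in arrs):
        raise ConfigurationError("every group needs n >= 1")
    total = sum(a.size for a in arrs)
    if total < 3:
        raise ConfigurationError("need total n >= 3")
    all_vals = np.concatenate(arrs)
    if np.all(all_vals == all_vals[0]):
        return 0.0, 1.0
    if method not in ("auto", "chi2", "exact"):
        raise ConfigurationError(f"unknown method {method!r}")
    if method == "exact" and total > EXACT_KW_TOTAL_N:
        raise ConfigurationError(
            f"exact permutation limited to total n <= {EXACT_KW_TOTAL_N}"
        )
    use_exact = method == "exact" or (method == "auto" and total <= EXACT_KW_TOTAL_N)
    h_obs = _kw_h(arrs)
    if not use_exact:
        res = sps.kruskal(*arrs)
        return float(res.statistic), float(res.pvalue)
    # enumerate all distinct assignments of the pooled values to group slots
    sizes = [a.size for a in arrs]
    idx_all = np.arange(total)
    count_ge = 0
    count_all = 0
    def recurse(remaining: np.ndarray, k: int, chosen: list[np.ndarray]):
        nonlocal count_ge, count_all
        if k == len(sizes) - 1:
            perm = chosen + [remaining]
            h = _kw_h([all_vals[i] for i in perm])
            count_all += 1
            if h >= h_obs - 1e-12:
                count_ge += 1
            return
        for comb in itertools.combinations(range(remaining.size), sizes[k]):
            sel = np.asarray(comb, dtype=int)
            mask = np.ones(remaining.size, dtype=bool)
            mask[sel] = False
            recurse(remaining[mask], k + 1, chosen + [remaining[sel]])
    recurse(idx_all, 0, [])
    return float(h_obs), count_ge / count_all


def rank_sum(a: GroupSample | Sequence[float], b: GroupSample | Sequence[float],
             mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney-U (Wilcoxon rank-sum) test; returns (U, p).

    ``mode="exact"`` enumerates the exact null distribution (requires no
    ties), ``"normal"`` uses the tie-corrected normal approximation with
    continuity correction, and ``"auto"`` picks exact for tie-free samples
    with total n <= 25, normal otherwise.
    """
    xa = np.asarray(a.values if isinstance(a, GroupSample) else a, dtype=float)
    xb = np.asarray(b.values if isinstance(b, GroupSample) else b, dtype=float)
    if xa.size < 1 or xb.size < 1:
        raise ConfigurationError("both samples need n >= 1")
    pooled = np.concatenate([xa, xb])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        mode = "exact" if (not has_ties and pooled.size <= EXACT_TOTAL_N) else "normal"
    if mode == "exact":
        if has_ties:
            raise ConfigurationError("exact mode requires tie-free samples")
        res = sps.mannwhitneyu(xa, xb, alternative="two-sided", method="exact")
    elif mode == "normal":
        res = sps.mannwhitneyu(xa, xb, alternative="two-sided", method="asymptotic")
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def adjust_pvalues(pvals: Sequence[float], method: str = "benjamini_hochberg") -> np.ndarray:
    """Multiplicity adjustment for one post-hoc family.

    ``benjamini_hochberg``: FDR step-up with enforced monotonicity;
    ``none``: identity.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ConfigurationError("p-values must lie in (0, 1]")
    if method == "none":
        return p.copy()
    if method == "benjamini_hochberg":
        return multipletests(p, method="fdr_bh")[1]
    raise ConfigurationError(f"unknown adjustment {method!r}")


def compare_groups(samples: Sequence[GroupSample],
                   designs: Sequence[ComparisonDesign],
                   adjust: str = "benjamini_hochberg",
                   posthoc_alpha: float | None = 0.05) -> list[GroupComparison]:
    """Run the full chain for each requested post-hoc family.

    For every design, samples are stratified by the ``within`` factors;
    within each stratum a Kruskal-Wallis omnibus test runs across the
    levels of the ``compare`` factor, followed by all pairwise rank-sum
    tests with per-family adjustment. If ``posthoc_alpha`` is given,
    post-hoc tests only run when the omnibus p is below it ("followed by"
    semantics); pass None to always run them.
    """
    if len(samples) < 2:
        raise ConfigurationError("need at least 2 groups")
    results: list[GroupComparison] = []
    for design in designs:
        strata: dict[tuple, list[GroupSample]] = {}
        for s in samples:
            if design.compare not in s.label:
                raise ConfigurationError(
                    f"sample {s.name()!r} lacks factor {design.compare!r}"
                )
            key = tuple(s.label.get(w) for w in design.within)
            strata.setdefault(key, []).append(s)
        for key, members in sorted(strata.items(), key=lambda kv: str(kv[0])):
            if len(members) < 2:
                continue
            h, p_omni = kruskal_wallis(members)
            rows = []
            run_posthoc = posthoc_alpha is None or p_omni < posthoc_alpha
            if run_posthoc:
                for ga, gb in itertools.combinations(members, 2):
                    u, p_raw = rank_sum(ga, gb)
                    rows.append({
                        "group_a": str(ga.label[design.compare]),
                        "group_b": str(gb.label[design.compare]),
                        "statistic": u,
                        "p_raw": p_raw,
                    })
            pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p_raw"])
            if len(pairwise):
                pairwise["p_adj"] = adjust_pvalues(pairwise["p_raw"].to_numpy(), adjust)
                pairwise["stars"] = [significance_stars(p) for p in pairwise["p_adj"]]
            else:
                pairwise["p_adj"] = pd.Series(dtype=float)
                pairwise["stars"] = pd.Series(dtype=str)
            results.append(GroupComparison(
                family=design.family,
                stratum={w: k for w, k in zip(design.within, key)},
                omnibus_h=h,
                omnibus_p=p_omni,
                pairwise=pairwise,
                adjustment=adjust,
            ))
    return results


def comparison_table(results: Sequence[GroupComparison]) -> pd.DataFrame:
    """Flatten GroupComparison records into one tidy row-per-pair table."""
    rows = []
    for res in results:
        stratum = "/".join(f"{k}={v}" for k, v in res.stratum.items()) or "-"
        rows.append({
            "family": res.family, "stratum": stratum, "group_a": "(omnibus)",
            "group_b": "", "statistic": res.omnibus_h, "p_raw": res.omnibus_p,
            "p_adj": res.omnibus_p, "stars": significance_stars(res.omnibus_p),
        })
        for _, r in res.pairwise.iterrows():
            rows.append({"family": res.family, "stratum": stratum, **r.to_dict()})
    return pd.DataFrame(rows)
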