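"""Nonparametric cohort comparison of ICN-pair correlation distributions.

Per functional domain, the within-domain ICN-pair values of each cohort
form one group; a tie-corrected Kruskal-Wallis omnibus test (alpha = 0.05)
is followed, only where significant, by Dunn's post hoc z tests on the
pooled ranks with Bonferroni correction. Inference is at the network level:
each ICN pair is one observation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p (df = k - 1).

    The degenerate all-identical case is defined as (H=0, p=1) rather than
    an error, since constant correlation blocks legitimately occur.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(groups)
    if pooled.size < 3:
        raise ValueError("need at least 3 values in total")
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    H, p = sps.kruskal(*groups)
    return float(H), float(p)


def _tie_term(ranks: np.ndarray) -> float:
    _, counts = np.unique(ranks, return_counts=True)
    return float((counts.astype(float) ** 3 - counts).sum())


def dunn_posthoc(groups, labels=None, adjust: str = "bonferroni",
                 n_comparisons: int | None = None) -> pd.DataFrame:
    """Dunn's pairwise z tests on pooled tie-corrected ranks.

    Returns one row per unordered group pair with the z statistic, the
    two-sided normal p, and ``p_adj = min(1, p_raw * m)`` where the
    Bonferroni multiplier ``m`` defaults to the number of pairs in this
    family (``n_comparisons`` overrides it, e.g. for a global family).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    if adjust not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [g.size for g in groups]
    offsets = np.cumsum([0] + sizes)
    mean_ranks = [ranks[offsets[i]:offsets[i + 1]].mean()
                  for i in range(len(groups))]
    # pooled rank variance with tie correction
    s2 = N * (N + 1) / 12.0 - _tie_term(ranks) / (12.0 * (N - 1))
    pairs = list(itertools.combinations(range(len(groups)), 2))
    m = n_comparisons if n_comparisons is not None else len(pairs)
    rows = []
    for a, b in pairs:
        se = np.sqrt(s2 * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p_raw * m) if adjust == "bonferroni" else p_raw
        rows.append({"group_a": labels[a], "group_b": labels[b],
                     "z": float(z), "p_raw": float(p_raw),
                     "p_adj": float(p_adj)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupComparisonResult:
    """Per-domain omnibus results and gated pairwise post hoc table.

    ``domain_table`` has one row per domain (H, p_kw, group sizes,
    significant); ``pairwise_table`` one row per (domain, cohort pair)
    where the omnibus was significant; ``domain_mask`` / ``pair_mask``
    are the boolean significance summaries at ``alpha``.
    """

    domain_table: pd.DataFrame
    pairwise_table: pd.DataFrame
    alpha: float
    domain_mask: dict[str, bool] = field(default_factory=dict)

    @property
    def significant_domains(self) -> tuple[str, ...]:
        return tuple(d for d, sig in self.domain_mask.items() if sig)

    @property
    def pair_mask(self) -> pd.DataFrame:
        """Domain x cohort-pair boolean significance matrix."""
        if self.pairwise_table.empty:
            return pd.DataFrame(index=sorted(self.domain_mask))
        t = self.pairwise_table.copy()
        t["pair"] = t["group_a"] + " vs " + t["group_b"]
        return (t.pivot_table(index="domain", columns="pair",
                              values="significant", aggfunc="any",
                              fill_value=False)
                .reindex(sorted(self.domain_mask), fill_value=False))


def compare_cohorts(values_by_cohort_by_domain: dict[str, dict[str, np.ndarray]],
                    alpha: float = 0.05,
                    bonferroni_scope: str = "per_domain"
                    ) -> GroupComparisonResult:
    """Kruskal-Wallis per domain across cohorts, Dunn post hoc where the
    omnibus is significant.

    ``values_by_cohort_by_domain[cohort][domain]`` is the vector of
    within-domain ICN-pair values for that cohort. All cohorts must cover
    the same domains. ``bonferroni_scope`` chooses the correction family:
    pairs within one domain (default) or pairs x domains ("global").
    """
    if bonferroni_scope not in ("per_domain", "global"):
        raise ValueError(f"unknown bonferroni scope {bonferroni_scope!r}")
    cohorts = list(values_by_cohort_by_domain)
    if len(cohorts) < 2:
        raise ValueError("need at least 2 cohorts")
    domains = list(values_by_cohort_by_domain[cohorts[0]])
    for c in cohorts:
        missing = set(domains) - set(values_by_cohort_by_domain[c])
        extra = set(values_by_cohort_by_domain[c]) - set(domains)
        if missing or extra:
            raise ValueError(f"cohort {c!r} domain mismatch: missing "
                             f"{sorted(missing)}, extra {sorted(extra)}")
    n_pairs = len(cohorts) * (len(cohorts) - 1) // 2
    global_m = n_pairs * len(domains)

    dom_rows, pair_rows = [], []
    domain_mask: dict[str, bool] = {}
    for d in domains:
        groups = [np.asarray(values_by_cohort_by_domain[c][d], dtype=float)
                  for c in cohorts]
        H, p = kruskal_wallis(groups)
        sig = bool(p < alpha)
        domain_mask[d] = sig
        dom_rows.append({"domain": d, "H": H, "p_kw": p,
                         "group_sizes": tuple(g.size for g in groups),
                         "significant": sig})
        if sig:
            m = global_m if bonferroni_scope == "global" else None
            table = dunn_posthoc(groups, labels=cohorts, n_comparisons=m)
            table.insert(0, "domain", d)
            table["significant"] = table["p_adj"] < alpha
            pair_rows.append(table)

    pairwise = (pd.concat(pair_rows, ignore_index=True) if pair_rows
                else pd.DataFrame(columns=["domain", "group_a", "group_b",
                                           "z", "p_raw", "p_adj",
                                           "significant"]))
    return GroupComparisonResult(domain_table=pd.DataFrame(dom_rows),
                                 pairwise_table=pairwise, alpha=alpha,
                                 domain_mask=domain_mask)
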