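"""Group statistics used throughout the study's figures.

Many-to-one comparisons against a shared control use Dunnett's procedure:
under the null, the vector of control-vs-group t statistics follows an
equicorrelated multivariate t with correlations r_ij = l_i*l_j,
l_i = sqrt(n_i/(n_i+n0)), which factorizes over a single shared standard
normal (the control mean) and the pooled-variance chi factor. The adjusted
p-value 1 - P(max_j |T_j| <= |t_i|) is computed by two-dimensional
Gauss-Hermite x Gauss-Legendre quadrature of that factorized integral —
exact for balanced and unbalanced designs alike. All-pairs comparisons use
the Tukey(-Kramer) studentized-range procedure. Relative qPCR expression
follows the comparative ΔΔCt method with geometric-mean summaries, and
expression screens count genes passing a strict fold-change cut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

DEFAULT_ALPHA = 0.05


@dataclass
class ComparisonRow:
    label: str
    estimate: float                      # difference of means
    statistic: float
    p_adjusted: float
    significant: bool


@dataclass
class GroupComparison:
    test: str                            # dunnett | tukey | student_t | paired_t
    comparisons: list[ComparisonRow] = field(default_factory=list)
    alpha: float = DEFAULT_ALPHA
    df: float = np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "comparison": [c.label for c in self.comparisons],
                "estimate": [c.estimate for c in self.comparisons],
                "statistic": [c.statistic for c in self.comparisons],
                "p_adjusted": [c.p_adjusted for c in self.comparisons],
                "significant": [c.significant for c in self.comparisons],
            }
        )

    @property
    def any_significant(self) -> bool:
        return any(c.significant for c in self.comparisons)


# ---------------------------------------------------------------------------
# Dunnett


def _pooled(groups):
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs n >= 2")
    ns = np.array([len(g) for g in groups])
    means = np.array([g.mean() for g in groups])
    ss = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df = int(ns.sum() - len(groups))
    s2 = ss / df
    if s2 <= 0:
        raise ValueError("zero pooled variance: comparisons undefined")
    return ns, means, s2, df


def dunnett_max_abs_cdf(q, lambdas, df, n_z: int = 96, n_u: int = 64):
    """P(max_j |T_j| <= q) for Dunnett's many-to-one statistics.

    ``lambdas`` are the factorization loadings sqrt(n_j/(n_j+n0)); ``df``
    the pooled-variance degrees of freedom. Vectorized over ``q``.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    lam = np.asarray(lambdas, dtype=float)
    if lam.size == 1:
        # single comparison: max|T| is just |t| with the pooled df
        return np.clip(1.0 - 2.0 * stats.t.sf(q, df), 0.0, 1.0)
    s = np.sqrt(1.0 - lam**2)
    # Gauss-Hermite for the shared control normal
    xz, wz = np.polynomial.hermite_e.hermegauss(n_z)
    wz = wz / np.sqrt(2 * np.pi)
    # Gauss-Legendre in probability space for U = chi_df / sqrt(df)
    xu, wu = np.polynomial.legendre.leggauss(n_u)
    pu = 0.5 * (xu + 1.0)
    wu = 0.5 * wu
    u = stats.chi.ppf(pu, df) / np.sqrt(df)

    # shapes: (k, nu, nz, nq)
    qu = u[None, :, None, None] * q[None, None, None, :]
    lz = (lam[:, None, None, None] * xz[None, None, :, None])
    sk = s[:, None, None, None]
    upper = (qu - lz) / sk
    lower = (-qu - lz) / sk
    prod = np.prod(stats.norm.cdf(upper) - stats.norm.cdf(lower), axis=0)
    inner = np.einsum("uzq,z->uq", prod, wz)
    res = np.einsum("uq,u->q", inner, wu)
    return np.clip(res, 0.0, 1.0)


def dunnett_critical(alpha, lambdas, df) -> float:
    """Two-sided critical value c with P(max|T| > c) = alpha."""
    f = lambda c: dunnett_max_abs_cdf(c, lambdas, df)[0] - (1 - alpha)
    return float(optimize.brentq(f, 0.5, 15.0, xtol=1e-8))


def dunnett_test(
    groups,
    control_index: int = 0,
    alpha: float = DEFAULT_ALPHA,
    labels: list[str] | None = None,
) -> GroupComparison:
    """Two-sided Dunnett many-to-one comparisons against a control group.

    Uses the pooled variance across all groups; each adjusted p-value is
    1 - P(max_j |T_j| <= |t_i|) under the equicorrelated multivariate-t
    null. For two groups this reduces exactly to the pooled two-sample
    t-test.
    """
    ns, means, s2, df = _pooled(groups)
    k = len(groups)
    idx = [i for i in range(k) if i != control_index]
    n0 = ns[control_index]
    lam = np.sqrt(ns[idx] / (ns[idx] + n0))
    se = np.sqrt(s2 * (1.0 / ns[idx] + 1.0 / n0))
    t_obs = (means[idx] - means[control_index]) / se
    p_adj = 1.0 - dunnett_max_abs_cdf(np.abs(t_obs), lam, df)
    labels = labels or [f"group{i}" for i in range(k)]
    rows = [
        ComparisonRow(
            label=f"{labels[control_index]} vs {labels[i]}",
            estimate=float(means[i] - means[control_index]),
            statistic=float(t),
            p_adjusted=float(p),
            significant=bool(p < alpha),
        )
        for i, t, p in zip(idx, t_obs, p_adj)
    ]
    return GroupComparison(test="dunnett", comparisons=rows, alpha=alpha, df=df)


# ---------------------------------------------------------------------------
# Tukey


def tukey_hsd(groups, alpha: float = DEFAULT_ALPHA, labels: list[str] | None = None) -> GroupComparison:
    """All-pairs Tukey(-Kramer) HSD with studentized-range adjusted p."""
    ns, means, s2, df = _pooled(groups)
    k = len(groups)
    labels = labels or [f"group{i}" for i in range(k)]
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(s2 * 0.5 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(means[j] - means[i]) / se
            p = float(stats.studentized_range.sf(q, k, df))
            p = float(np.clip(p, 0.0, 1.0))
            rows.append(
                ComparisonRow(
                    label=f"{labels[i]} vs {labels[j]}",
                    estimate=float(means[j] - means[i]),
                    statistic=float(q),
                    p_adjusted=p,
                    significant=bool(p < alpha),
                )
            )
    return GroupComparison(test="tukey", comparisons=rows, alpha=alpha, df=df)


# ---------------------------------------------------------------------------
# t tests


def t_tests(a, b, paired: bool = False, alpha: float = DEFAULT_ALPHA) -> GroupComparison:
    """Two-sided Student (pooled) or paired t-test between two samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per sample")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal lengths")
        d = a - b
        if np.allclose(d.std(ddof=1), 0):
            warnings.warn("degenerate (zero-variance) differences; p set to 1")
            t, p, df = 0.0, 1.0, len(d) - 1
        else:
            res = stats.ttest_rel(a, b)
            t, p, df = res.statistic, res.pvalue, len(d) - 1
        name = "paired_t"
    else:
        res = stats.ttest_ind(a, b, equal_var=True)
        t, p, df = res.statistic, res.pvalue, len(a) + len(b) - 2
        if not np.isfinite(t):
            warnings.warn("degenerate (zero-variance) samples; p set to 1")
            t, p = 0.0, 1.0
        name = "student_t"
    row = ComparisonRow(
        label="a vs b",
        estimate=float(a.mean() - b.mean()),
        statistic=float(t),
        p_adjusted=float(p),
        significant=bool(p < alpha),
    )
    return GroupComparison(test=name, comparisons=[row], alpha=alpha, df=df)


# ---------------------------------------------------------------------------
# ΔΔCt relative expression


@dataclass
class RelExprResult:
    gene: str
    per_sample: pd.DataFrame             # sample, group, delta_ct, ddct, rq
    group_summary: pd.DataFrame          # group, geo_mean, geo_sd, n
    excluded_samples: list[str] = field(default_factory=list)


def ddct(
    ct_table: pd.DataFrame,
    reference_gene: str,
    calibrator_group: str,
    target_gene: str | None = None,
) -> RelExprResult | dict[str, RelExprResult]:
    """Comparative ΔΔCt relative quantification.

    ``ct_table`` is tidy with columns (sample, group, gene, ct). For each
    sample, ΔCt = Ct_target - Ct_reference; ΔΔCt is taken against the mean
    ΔCt of the calibrator group, so the calibrator's geometric mean RQ is
    exactly 1. RQ = 2^(-ΔΔCt). Group summaries are geometric mean and
    geometric SD (sample SD of log2 RQ, exponentiated). Samples whose Ct is
    missing (below the detection limit) are excluded with a warning.
    """
    required = {"sample", "group", "gene", "ct"}
    if not required.issubset(ct_table.columns):
        raise ValueError(f"ct_table needs columns {sorted(required)}")
    genes = [g for g in ct_table["gene"].unique() if g != reference_gene]
    if target_gene is not None:
        genes = [target_gene]
    out = {}
    for gene in genes:
        out[gene] = _ddct_one(ct_table, reference_gene, calibrator_group, gene)
    return out[target_gene] if target_gene is not None else out


def _ddct_one(ct_table, reference_gene, calibrator_group, gene):
    ref = ct_table[ct_table["gene"] == reference_gene].set_index("sample")["ct"]
    tgt = ct_table[ct_table["gene"] == gene].set_index("sample")
    if ref.isna().any():
        bad = sorted(ref[ref.isna()].index)
        raise ValueError(f"reference gene Ct missing for samples {bad}")
    missing = ref.index.difference(tgt.index)
    if len(missing):
        raise ValueError(f"reference gene absent for samples {sorted(missing)}")

    excluded = sorted(tgt.index[tgt["ct"].isna()])
    if excluded:
        warnings.warn(
            f"{gene}: {len(excluded)} sample(s) under the detection limit removed"
        )
    tgt = tgt.dropna(subset=["ct"])
    dct = tgt["ct"] - ref.loc[tgt.index]
    cal = dct[tgt["group"] == calibrator_group]
    if cal.empty:
        raise ValueError(f"no calibrator samples for gene {gene}")
    ddct_vals = dct - cal.mean()
    rq = np.power(2.0, -ddct_vals)
    per_sample = pd.DataFrame(
        {
            "sample": tgt.index,
            "group": tgt["group"].values,
            "delta_ct": dct.values,
            "ddct": ddct_vals.values,
            "rq": rq.values,
        }
    ).reset_index(drop=True)
    rows = []
    for grp, sub in per_sample.groupby("group", sort=False):
        logs = np.log2(sub["rq"].values)
        gsd = float(2.0 ** np.std(logs, ddof=1)) if len(logs) > 1 else np.nan
        rows.append(
            {
                "group": grp,
                "geo_mean": float(2.0 ** np.mean(logs)),
                "geo_sd": gsd,
                "n": len(sub),
            }
        )
    return RelExprResult(
        gene=gene,
        per_sample=per_sample,
        group_summary=pd.DataFrame(rows),
        excluded_samples=excluded,
    )


# ---------------------------------------------------------------------------
# fold-change DEG screening


@dataclass
class DEGResult:
    contrasts: dict[str, dict[str, list[str]]]   # name -> {"up": [...], "down": [...]}
    fc_threshold: float

    def genes(self, contrast: str) -> set[str]:
        d = self.contrasts[contrast]
        return set(d["up"]) | set(d["down"])

    def counts(self) -> dict[str, int]:
        return {c: len(self.genes(c)) for c in self.contrasts}

    def intersection(self, *names: str) -> set[str]:
        names = names or tuple(self.contrasts)
        sets = [self.genes(n) for n in names]
        return set.intersection(*sets)


def deg_filter_and_venn(
    expr: pd.DataFrame,
    groups: pd.Series,
    contrasts: list[tuple[str, str]],
    fc_threshold: float = 2.0,
) -> DEGResult:
    """Count genes changed more than ``fc_threshold``-fold per contrast.

    ``expr`` is genes x samples on a linear scale; ``groups`` maps sample
    to group. For contrast (case, control) the fold change is the ratio of
    arithmetic group means; a gene is differential iff fold > threshold or
    fold < 1/threshold, strictly. Intersections across contrasts give the
    Venn counts.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must exceed 1")
    missing = set(groups.index) - set(expr.columns)
    if missing:
        raise ValueError(f"samples missing from matrix: {sorted(missing)}")
    result: dict[str, dict[str, list[str]]] = {}
    for case, control in contrasts:
        mc = expr[groups.index[groups == case]].mean(axis=1)
        m0 = expr[groups.index[groups == control]].mean(axis=1)
        fold = mc / m0
        up = sorted(fold.index[fold > fc_threshold])
        down = sorted(fold.index[fold < 1.0 / fc_threshold])
        result[f"{case}_vs_{control}"] = {"up": up, "down": down}
    return DEGResult(contrasts=result, fc_threshold=fc_threshold)
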