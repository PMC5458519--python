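"""Moderated-t differential PSI between sample groups.

The per-event variance is shrunk toward a prior estimated across events by
empirical Bayes.  Writing ``s²_g`` for the pooled two-group residual variance
of event g on df residual degrees of freedom, the model takes

    s²_g | σ²_g  ~  σ²_g · χ²_df / df,      1/σ²_g  ~  χ²_d0 / (d0 · s0²),

so that marginally ``s²_g / s0² ~ F(df, d0)``.  The hyper-parameters
``(d0, s0²)`` are fit by moment matching on ``log s²`` using digamma /
trigamma identities for the log of a chi-square.  The posterior variance

    s̃²_g = (d0·s0² + df·s²_g) / (d0 + df)

replaces ``s²_g`` in the two-sample t statistic, which then has df + d0
degrees of freedom (the normal limit as d0 → ∞).

Significance is assessed after Benjamini–Hochberg correction; q ≤ 0.05 is
the default cutoff throughout the pipeline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .formats_io import AnnotationModel, SiteKey
from .psi import JunctionKey, acceptor_site, donor_site

__all__ = [
    "ShrinkagePrior",
    "estimate_prior",
    "moderated_t_test",
    "bh_adjust",
    "AnnotationIndex",
    "classify_junction",
    "classify_event",
    "summarize_events",
]


# ---------------------------------------------------------------------------
# Empirical-Bayes variance shrinkage
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShrinkagePrior:
    """Hyper-parameters of the variance prior.

    ``d0`` is the prior degrees of freedom (``math.inf`` when the observed
    spread of log-variances is no larger than sampling noise under a common
    variance) and ``s0_sq`` the prior variance.  The fitted prior always has
    ``d0 > 0``; ``d0 = 0`` is accepted as a degenerate no-shrinkage prior,
    under which the moderated t reduces to the classic pooled-variance
    two-sample t.
    """

    d0: float
    s0_sq: float

    def __post_init__(self):
        if not (self.d0 >= 0):
            raise ValueError(f"d0 must be >= 0, got {self.d0}")
        if not (self.s0_sq > 0):
            raise ValueError(f"s0_sq must be > 0, got {self.s0_sq}")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration on 1/y scale."""
    if x <= 0:
        raise ValueError("trigamma inverse needs a positive argument")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def estimate_prior(
    sample_variances: Sequence[float] | np.ndarray,
    residual_df: float | np.ndarray,
) -> ShrinkagePrior:
    """Fit (d0, s0²) by moment matching on the log sample variances.

    ``residual_df`` is a scalar (equal residual df across events, the usual
    balanced-design case) or a per-event vector.  Events with non-positive
    variance carry no information about the scale and are excluded from the
    fit; if every variance is zero this raises.
    """
    s2 = np.asarray(sample_variances, dtype=float)
    df = np.broadcast_to(np.asarray(residual_df, dtype=float), s2.shape)
    ok = (s2 > 0) & (df > 0)
    if ok.sum() == 0:
        raise ValueError("all sample variances are zero; cannot fit a variance prior")
    s2, df = s2[ok], df[ok]
    if s2.size < 2:
        raise ValueError("need >=2 events with positive variance")
    # log s2 = log sigma2 + log(chi2_df/df); correct the chi-square log-bias
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0).mean())
    if e_var <= 0:
        # no excess spread beyond sampling noise: common-variance limit
        return ShrinkagePrior(math.inf, float(s2.mean()))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = math.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return ShrinkagePrior(d0, s0_sq)


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values (q-values).

    q_(i) = min over j >= i of min(1, p_(j)·m/j) in the sorted-p order; ties
    resolve identically regardless of input order (the adjusted value is a
    function of the p-value alone).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def moderated_t_test(
    psi_matrix: pd.DataFrame,
    group_labels: Mapping[str, str] | pd.Series,
    prior: ShrinkagePrior | None = None,
    *,
    group_order: tuple[str, str] | None = None,
    min_samples: int = 2,
) -> pd.DataFrame:
    """Moderated two-sample t-test per event (row) between two sample groups.

    Parameters
    ----------
    psi_matrix:
        events × samples table of PSI values; NaN marks undefined PSI.
    group_labels:
        sample name → group name; exactly two groups must be present among
        the matrix columns.
    prior:
        optional pre-fit :class:`ShrinkagePrior`; fit from the testable
        events' variances when omitted.  ``ShrinkagePrior`` with ``d0 = 0``
        is not representable (d0 > 0 invariant); to recover the classic
        pooled-variance t pass ``prior=None`` and use
        :func:`classic_t_test`, or a prior with tiny d0.
    group_order:
        (group1, group2); delta_psi = mean(group2) − mean(group1).  Defaults
        to sorted group names.

    Events with fewer than ``min_samples`` defined values in either group are
    reported untestable (NaN statistics, ``testable=False``) rather than
    imputed.
    """
    labels = pd.Series(group_labels)
    labels = labels[labels.index.intersection(psi_matrix.columns)]
    groups = sorted(labels.unique()) if group_order is None else list(group_order)
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    cols1 = labels.index[labels == groups[0]]
    cols2 = labels.index[labels == groups[1]]
    if len(cols1) == 0 or len(cols2) == 0:
        raise ValueError(f"empty group among {groups}")

    x1 = psi_matrix[cols1].to_numpy(dtype=float)
    x2 = psi_matrix[cols2].to_numpy(dtype=float)
    n1 = (~np.isnan(x1)).sum(axis=1)
    n2 = (~np.isnan(x2)).sum(axis=1)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows -> NaN mean
        m1 = np.nanmean(x1, axis=1)
        m2 = np.nanmean(x2, axis=1)
        ss1 = np.nansum((x1 - m1[:, None]) ** 2, axis=1)
        ss2 = np.nansum((x2 - m2[:, None]) ** 2, axis=1)
    df = n1 + n2 - 2
    testable = (n1 >= min_samples) & (n2 >= min_samples) & (df >= 1)
    s2 = np.full(len(psi_matrix), np.nan)
    s2[testable] = (ss1[testable] + ss2[testable]) / df[testable]
    delta = m2 - m1

    if prior is None:
        prior = estimate_prior(s2[testable], df[testable])

    s2_post = np.full_like(s2, np.nan)
    df_total = np.full_like(s2, np.nan)
    if math.isinf(prior.d0):
        s2_post[testable] = prior.s0_sq
        df_total[testable] = np.inf
    else:
        s2_post[testable] = (prior.d0 * prior.s0_sq + df[testable] * s2[testable]) / (
            prior.d0 + df[testable]
        )
        df_total[testable] = df[testable] + prior.d0

    se = np.sqrt(s2_post * (1.0 / np.maximum(n1, 1) + 1.0 / np.maximum(n2, 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, delta / se, np.where(delta == 0, 0.0, np.nan))
    t_mod = np.where(testable, t_mod, np.nan)
    p = np.full_like(s2, np.nan)
    fin = testable & np.isfinite(t_mod)
    norm_df = fin & ~np.isfinite(df_total)
    t_df = fin & np.isfinite(df_total)
    p[t_df] = 2.0 * stats.t.sf(np.abs(t_mod[t_df]), df_total[t_df])
    p[norm_df] = 2.0 * stats.norm.sf(np.abs(t_mod[norm_df]))

    q = np.full_like(p, np.nan)
    has_p = ~np.isnan(p)
    if has_p.any():
        q[has_p] = bh_adjust(p[has_p])

    out = pd.DataFrame(
        {
            "delta_psi": delta,
            "t_mod": t_mod,
            "df_total": df_total,
            "p": p,
            "q": q,
            "s2": s2,
            "s2_post": s2_post,
            "mean_1": m1,
            "mean_2": m2,
            "n1": n1,
            "n2": n2,
            "testable": testable,
        },
        index=psi_matrix.index,
    )
    out.attrs["prior"] = prior
    out.attrs["groups"] = tuple(groups)
    return out


def classic_t_test(x1: np.ndarray, x2: np.ndarray) -> tuple[float, float]:
    """Textbook pooled-variance two-sample t (equal-variance Student's t)."""
    t, p = stats.ttest_ind(x2, x1, equal_var=True)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Event classification against the annotation
# ---------------------------------------------------------------------------


@dataclass
class AnnotationIndex:
    """Site/interval lookups derived from an :class:`AnnotationModel`."""

    introns: set[JunctionKey]
    donor_sites: set[SiteKey]
    acceptor_sites: set[SiteKey]
    skip_junctions: set[JunctionKey]  # single-cassette-exon skip junctions

    @classmethod
    def build(cls, model: AnnotationModel) -> "AnnotationIndex":
        introns: set[JunctionKey] = set()
        donors: set[SiteKey] = set()
        acceptors: set[SiteKey] = set()
        skips: set[JunctionKey] = set()
        for tx in model:
            iv = tx.introns()  # ascending genomic order
            for s, e in iv:
                key = (tx.chrom, s, e, tx.strand)
                introns.add(key)
                donors.add(donor_site(key))
                acceptors.add(acceptor_site(key))
            # skipping exon between introns k and k+1 merges their outer ends
            for (s1, _), (_, e2) in zip(iv, iv[1:]):
                skips.add((tx.chrom, s1, e2, tx.strand))
        return cls(introns, donors, acceptors, skips)


def classify_junction(key: JunctionKey, index: AnnotationIndex) -> str:
    """Classify one junction: canonical / ES / alt5 / alt3 / other.

    ES requires the junction to merge the outer boundaries of two annotated
    introns flanking one annotated exon; a junction sharing only its donor
    with the annotation has a novel acceptor (alt3) and vice versa (alt5).
    """
    if key in index.introns:
        return "canonical"
    if key in index.skip_junctions:
        return "ES"
    donor_known = donor_site(key) in index.donor_sites
    acceptor_known = acceptor_site(key) in index.acceptor_sites
    if donor_known and not acceptor_known:
        return "alt3"
    if acceptor_known and not donor_known:
        return "alt5"
    return "other"


def classify_event(event: tuple[str, object], index: AnnotationIndex) -> str:
    """Classify a differential event: ('junction', JunctionKey) or ('boundary', SiteKey).

    A boundary-count event at an annotated 3' splice site is intron
    retention (IR); anything unanchored is 'other'.
    """
    kind, key = event
    if kind == "boundary":
        return "IR" if key in index.acceptor_sites else "other"
    if kind == "junction":
        return classify_junction(key, index)
    raise ValueError(f"unknown event kind {kind!r}")


# ---------------------------------------------------------------------------
# Significant-event summaries
# ---------------------------------------------------------------------------


def summarize_events(
    diff_results: pd.DataFrame,
    q_max: float = 0.05,
    epsilon: float = 0.01,
) -> pd.DataFrame:
    """Per-category counts, fractions and log2 fold-change distributions.

    ``diff_results`` needs columns category, q, mean_1 (control PSI) and
    mean_2 (treatment PSI).  The fold change is defined on PSI with a
    pseudocount: log2((psi_treat + ε)/(psi_ctrl + ε)).  Box statistics are
    quartiles with 1.5×IQR whisker bounds.
    """
    sig = diff_results[(diff_results["q"] <= q_max) & diff_results["q"].notna()].copy()
    if len(sig):
        sig["log2fc"] = np.log2((sig["mean_2"] + epsilon) / (sig["mean_1"] + epsilon))
    rows = []
    total = len(sig)
    for cat, grp in sig.groupby("category"):
        fc = grp["log2fc"].to_numpy()
        q1, med, q3 = np.percentile(fc, [25, 50, 75]) if len(fc) else (np.nan,) * 3
        iqr = q3 - q1
        rows.append(
            {
                "category": cat,
                "count": len(grp),
                "fraction": len(grp) / total,
                "log2fc_median": med,
                "log2fc_q1": q1,
                "log2fc_q3": q3,
                "whisker_lo": q1 - 1.5 * iqr,
                "whisker_hi": q3 + 1.5 * iqr,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "category",
            "count",
            "fraction",
            "log2fc_median",
            "log2fc_q1",
            "log2fc_q3",
            "whisker_lo",
            "whisker_hi",
        ],
    )
    out.attrs["q_max"] = q_max
    out.attrs["epsilon"] = epsilon
    out.attrs["n_significant"] = total
    return out
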