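"""Agreement statistics between estimated and directly measured pressures.

Descriptive measures
--------------------
RMSD = sqrt(mean((est - meas)^2)), ME = mean(est - meas) and
RME = 100 * mean((est - meas)/meas) summarise accuracy per experiment.

Concordance
-----------
Lin's concordance correlation coefficient (CCC) for repeated measures is
computed from the variance components of the crossed
subject x method x repeat design:

    CCC = (sigma_s^2 + sigma_sn^2)
        / (sigma_s^2 + sigma_sn^2 + sigma_sm^2 + sigma_mn^2 + sigma_e^2)

with s = subject, m = method, n = measurement number.  Components are
estimated by balanced three-way ANOVA method of moments (negative moment
estimates truncated at zero, pre-truncation values retained in the
result); the confidence interval is a percentile bootstrap over subjects.
An external variance-components estimator (e.g. REML) can be plugged in
via ``components_estimator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "PerformanceMeasures",
    "VarianceComponents",
    "ConcordanceResult",
    "performance_measures",
    "lin_ccc",
    "anova_variance_components",
    "lin_ccc_repeated",
]


@dataclass(frozen=True)
class PerformanceMeasures:
    rmsd: float  # mmHg
    me: float  # mmHg
    rme: float  # percent
    n: int


@dataclass(frozen=True)
class VarianceComponents:
    """Crossed-design components; ``raw`` holds pre-truncation estimates."""

    s: float
    sn: float
    sm: float
    mn: float
    e: float
    raw: dict = field(default_factory=dict)

    def ccc(self) -> float:
        denom = self.s + self.sn + self.sm + self.mn + self.e
        if denom <= 0:
            raise ValueError("degenerate design: total variance is zero")
        return (self.s + self.sn) / denom


@dataclass(frozen=True)
class ConcordanceResult:
    ccc: float
    ci_low: float
    ci_high: float
    components: VarianceComponents
    n_subjects: int
    n_bootstrap: int
    dropped_subjects: tuple = ()


def performance_measures(p_est, p_meas) -> PerformanceMeasures:
    """RMSD, ME and RME between estimated and measured pressures [mmHg]."""
    est = np.asarray(p_est, dtype=float)
    meas = np.asarray(p_meas, dtype=float)
    if est.shape != meas.shape or est.ndim != 1 or est.size == 0:
        raise ValueError("p_est and p_meas must be equal-length nonempty 1-D")
    zero = np.nonzero(meas == 0)[0]
    if zero.size:
        raise ValueError(f"measured pressure is zero at index {zero[0]}; "
                         "relative mean error is undefined")
    d = est - meas
    return PerformanceMeasures(rmsd=float(np.sqrt(np.mean(d * d))),
                               me=float(np.mean(d)),
                               rme=float(100.0 * np.mean(d / meas)),
                               n=est.size)


def lin_ccc(x, y) -> float:
    """Classic bivariate Lin concordance: 2 s_xy / (s_x^2 + s_y^2 + (mx-my)^2).

    Population (ddof=0) moments, as in Lin's original definition.  Used as
    the closed-form cross-check of the repeated-measures estimator when
    each subject contributes one pair.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must be equal-length with at least 2 pairs")
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    return float(2.0 * sxy / (x.var() + y.var() + (x.mean() - y.mean()) ** 2))


def _balanced_cube(table: pd.DataFrame) -> tuple[np.ndarray, list]:
    """(subject, method, repeat) value cube from a long table; drops
    subjects with incomplete method x repeat cells."""
    req = {"subject", "method", "repeat", "value"}
    if not req.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(req)}")
    methods = sorted(table["method"].unique())
    repeats = sorted(table["repeat"].unique())
    if len(methods) < 2:
        raise ValueError("at least 2 methods are required")
    full = len(methods) * len(repeats)
    counts = table.groupby("subject").size()
    keep = counts[counts == full].index
    dropped = sorted(set(table["subject"].unique()) - set(keep))
    if len(keep) < 3:
        raise ValueError("fewer than 3 subjects with complete "
                         "method x repeat measurements")
    sub = table[table["subject"].isin(keep)]
    cube = (sub.pivot_table(index="subject", columns=["method", "repeat"],
                            values="value", aggfunc="mean")
            .to_numpy().reshape(len(keep), len(methods), len(repeats)))
    return cube, dropped


def anova_variance_components(table: pd.DataFrame
                              ) -> tuple[VarianceComponents, list]:
    """Method-of-moments components of the crossed three-way design.

    One observation per (subject, method, repeat) cell; the three-way
    interaction is confounded with the residual.  Mean squares are equated
    to their random-model expectations and solved; negative solutions are
    truncated at zero with the raw values recorded.
    """
    y, dropped = _balanced_cube(table)
    return _components_from_cube(y), dropped


def _components_from_cube(y: np.ndarray) -> VarianceComponents:
    S, M, N = y.shape
    mu = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_m = y.mean(axis=(0, 2))
    m_n = y.mean(axis=(0, 1))
    m_sm = y.mean(axis=2)
    m_sn = y.mean(axis=1)
    m_mn = y.mean(axis=0)
    ss_s = M * N * np.sum((m_s - mu) ** 2)
    ss_m = S * N * np.sum((m_m - mu) ** 2)
    ss_n = S * M * np.sum((m_n - mu) ** 2)
    ss_sm = N * np.sum((m_sm - m_s[:, None] - m_m[None, :] + mu) ** 2)
    ss_sn = M * np.sum((m_sn - m_s[:, None] - m_n[None, :] + mu) ** 2)
    ss_mn = S * np.sum((m_mn - m_m[:, None] - m_n[None, :] + mu) ** 2)
    ss_tot = np.sum((y - mu) ** 2)
    ss_e = ss_tot - ss_s - ss_m - ss_n - ss_sm - ss_sn - ss_mn
    df_e = (S - 1) * (M - 1) * (N - 1)
    ms_e = ss_e / df_e if df_e > 0 else 0.0
    ms_s = ss_s / (S - 1)
    ms_sm = ss_sm / ((S - 1) * (M - 1))
    # with a single repeat the sn/mn interactions have no degrees of freedom
    # and the residual is confounded with sm: it is absorbed there
    raw = {
        "e": ms_e,
        "sm": (ms_sm - ms_e) / N,
        "sn": (ss_sn / ((S - 1) * (N - 1)) - ms_e) / M if N > 1 else 0.0,
        "mn": (ss_mn / ((M - 1) * (N - 1)) - ms_e) / S if N > 1 else 0.0,
    }
    raw["s"] = (ms_s - N * max(raw["sm"], 0.0) - M * max(raw["sn"], 0.0)
                - ms_e) / (M * N)
    return VarianceComponents(
        s=max(raw["s"], 0.0), sn=max(raw["sn"], 0.0), sm=max(raw["sm"], 0.0),
        mn=max(raw["mn"], 0.0), e=max(raw["e"], 0.0), raw=raw)


def lin_ccc_repeated(table: pd.DataFrame, n_bootstrap: int = 2000,
                     seed: int = 0, ci_level: float = 0.95,
                     components_estimator: Callable[[pd.DataFrame],
                                                    tuple] | None = None
                     ) -> ConcordanceResult:
    """Repeated-measures Lin CCC from crossed variance components.

    ``table`` is long-format with columns (subject, method, repeat, value).
    The CI resamples subjects with replacement (percentile bootstrap);
    degenerate bootstrap draws (zero total variance) are skipped.
    """
    estimator = components_estimator or anova_variance_components
    comp, dropped = estimator(table)
    ccc = comp.ccc()
    rng = np.random.default_rng(seed)
    subjects = np.array(sorted(table["subject"].unique()))
    boots = []
    if components_estimator is None:
        # fast path: resample rows of the balanced cube directly
        cube, _ = _balanced_cube(table)
        n_s = cube.shape[0]
        for _ in range(n_bootstrap):
            draw = rng.integers(0, n_s, size=n_s)
            try:
                boots.append(_components_from_cube(cube[draw]).ccc())
            except ValueError:
                continue
    else:
        for _ in range(n_bootstrap):
            draw = rng.choice(subjects, size=subjects.size, replace=True)
            parts = []
            for new_id, s in enumerate(draw):
                part = table[table["subject"] == s].copy()
                part["subject"] = new_id
                parts.append(part)
            try:
                bcomp, _ = estimator(pd.concat(parts, ignore_index=True))
                boots.append(bcomp.ccc())
            except ValueError:
                continue
    if boots:
        q = (1.0 - ci_level) / 2.0
        lo, hi = np.quantile(boots, [q, 1.0 - q])
        lo, hi = min(lo, ccc), max(hi, ccc)
    else:
        lo = hi = ccc
    return ConcordanceResult(ccc=float(ccc), ci_low=float(lo),
                             ci_high=float(hi), components=comp,
                             n_subjects=int(subjects.size),
                             n_bootstrap=n_bootstrap,
                             dropped_subjects=tuple(dropped))
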