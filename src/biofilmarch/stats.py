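"""Supporting statistics: pairwise Mann–Whitney matrices, correlation,
five-number summaries, and profile-roughness parameters."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class PairwiseTestMatrix:
    """Symmetric p-value matrix of pairwise two-sided Mann–Whitney U tests.

    Diagonal entries are NaN (a sample against itself is not a test);
    ``reject[i, j]`` is True when ``p[i, j] < alpha``.
    """

    labels: list[str]
    p: np.ndarray
    reject: np.ndarray
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p, index=self.labels, columns=self.labels)

    def to_records(self) -> dict[str, dict[str, float | bool]]:
        out: dict[str, dict[str, float | bool]] = {}
        for i, a in enumerate(self.labels):
            for j, b in enumerate(self.labels):
                if j <= i:
                    continue
                out[f"{a}|{b}"] = {"p": float(self.p[i, j]), "reject": bool(self.reject[i, j])}
        return out


def _mwu_p(x: np.ndarray, y: np.ndarray) -> float:
    # exact null by enumeration only when both samples are small and
    # tie-free; the normal approximation (tie + continuity corrected)
    # otherwise.
    exact_ok = len(x) <= 8 and len(y) <= 8 and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if exact_ok else "asymptotic"
    return float(sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def mann_whitney_matrix(
    groups: list[np.ndarray], labels: list[str] | None = None, alpha: float = 0.05
) -> PairwiseTestMatrix:
    """All-pairs two-sided Mann–Whitney U tests at significance ``alpha``.

    Used to ask whether samples (e.g. the 1600-point roughness profiles
    of different tesserae, or per-slice morphometrics of different
    sampling points) are statistically indistinguishable in median.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    for g in groups:
        if g.size < 1:
            raise ValueError("every group needs at least one observation")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    k = len(groups)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            p[i, j] = p[j, i] = _mwu_p(groups[i], groups[j])
    reject = p < alpha
    return PairwiseTestMatrix(labels=list(labels), p=p, reject=reject, alpha=alpha)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation between two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length series of at least 3 points")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a zero-variance series")
    return float(sps.pearsonr(x, y).statistic)


def five_number_summary(data: np.ndarray) -> tuple[float, float, float, float, float]:
    """(min, Q1, median, Q3, max) with linearly interpolated quartiles.

    Quartiles use the inclusive linear-interpolation rule; the whisker
    ends are the sample minimum and maximum.
    """
    d = np.asarray(data, dtype=float)
    if d.size < 1:
        raise ValueError("need at least one observation")
    q1, med, q3 = np.quantile(d, [0.25, 0.5, 0.75], method="linear")
    return float(d.min()), float(q1), float(med), float(q3), float(d.max())


@dataclass
class RoughnessSummary:
    """ISO-4287-style amplitude parameters of a height profile (length units)."""

    ra: float  # mean absolute deviation
    rq: float  # root-mean-square deviation
    rz: float  # mean peak-to-valley over sampling segments
    rt: float  # total peak-to-valley
    n_points: int


def roughness_parameters(profile: np.ndarray, n_segments: int = 5) -> RoughnessSummary:
    """Amplitude roughness parameters of a raw, mean-centered profile.

    After subtracting the profile mean: Ra = mean |z|, Rq = √(mean z²),
    Rt = max z − min z, and Rz = mean over ``n_segments`` equal contiguous
    segments of each segment's peak-to-valley height.  No profile
    filtering is applied; parameters describe the raw trace.
    """
    z = np.asarray(profile, dtype=float)
    if z.size < 2:
        raise ValueError("profile needs at least 2 points")
    z = z - z.mean()
    ra = float(np.abs(z).mean())
    rq = float(np.sqrt(np.mean(z**2)))
    rt = float(z.max() - z.min())
    if z.size < n_segments:
        warnings.warn(
            f"profile shorter than {n_segments} segments; using {z.size} segments", stacklevel=2
        )
        n_segments = z.size
    seg_ptp = [float(seg.max() - seg.min()) for seg in np.array_split(z, n_segments)]
    rz = float(np.mean(seg_ptp))
    return RoughnessSummary(ra=ra, rq=rq, rz=rz, rt=rt, n_points=int(z.size))
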