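"""Dimensionless architecture quantities, aggregation, and classification.

Three per-slice quantities, all in [0, 1], describe how a phototrophic
population occupies slice j of a Z-stack:

* coverage fraction      𝒜 = A / a            (biomass area over slice area)
* linear-measure ratio   ℒ = (A/P) / (√a / 4)  (pattern's characteristic
  linear measure A/P against that of the full square slice, a/(4√a) = √a/4)
* normalized fractal dim 𝒟 = D_B / 2

Compact mats score near 1 on all three; reticulate networks near 0.  A
strain's N-slice series is collapsed by three aggregation operators —
maximum, arithmetic mean, and a Gaussian-weighted mean whose weights peak
at ordinal position λ(1+N) (λ = 0.5 centers them on the mid-depth slices,
where biomass concentrates) — then rescaled across strains so the best
strain per quantity × operator scores exactly 1.  The colonization index
I_C of a strain is the mean of its three rescaled quantities under one
operator; I_C < 0.5 marks a porous colonizer, 0.7 ≤ I_C a compact one,
and values between are intermediate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

QUANTITIES = ("coverage", "linear_ratio", "fractal")
OPERATORS = ("max", "mean", "weighted")

POROUS_BELOW = 0.5
COMPACT_FROM = 0.7
LABELS = ("porous", "intermediate", "compact")


def coverage_fraction(area: float, total_area: float) -> float:
    """𝒜: fraction of the slice (or substrate) covered by biomass."""
    if total_area <= 0:
        raise ValueError("total area must be positive")
    if area < 0 or area > total_area:
        raise ValueError(
            f"biomass area {area} outside [0, {total_area}] — check units/conventions"
        )
    return float(area / total_area)


def linear_ratio(area: float, perimeter: float, slice_area: float, clamp: bool = True) -> float:
    """ℒ: pattern linear measure A/P over the slice's √a/4 (i.e. 4A/(P√a)).

    Zero by convention for an empty pattern.  The ratio is clamped to
    [0, 1]; discretized contours of very compact patterns can exceed 1
    slightly because a block's border contour is shorter than the ideal
    boundary of the same area.
    """
    if slice_area <= 0:
        raise ValueError("slice area must be positive")
    if area < 0 or perimeter < 0:
        raise ValueError("area and perimeter must be nonnegative")
    if area == 0:
        return 0.0
    if perimeter == 0:
        raise ValueError("nonzero area with zero perimeter is geometrically impossible")
    raw = (area / perimeter) / (np.sqrt(slice_area) / 4.0)
    return float(np.clip(raw, 0.0, 1.0)) if clamp else float(raw)


def normalized_fractal(d_b: float) -> float:
    """𝒟 = D_B / 2 for a planar pattern (D_B already clamped to [0, 2])."""
    if not 0.0 <= d_b <= 2.0:
        raise ValueError(f"D_B must lie in [0, 2] (clamped upstream); got {d_b}")
    return float(d_b / 2.0)


@dataclass
class WeightScheme:
    """Gaussian ordinal weights over the N slices of a stack.

    μ_N = λ(1+N) is the ordinal position of maximum weight and σ_N the
    population standard deviation of the ordinals 1..N; unnormalized
    weights are the Gaussian density exp(−(j−μ_N)²/(2σ_N²)) at each
    ordinal, normalized to sum to one.
    """

    n: int
    lam: float
    mu: float
    sigma: float
    weights: np.ndarray


def gaussian_weights(n: int, lam: float = 0.5, literal_sigma: bool = False) -> WeightScheme:
    """Normalized Gaussian weights over slice ordinals 1..n.

    λ = 0.5 (default) makes the weights symmetric about the median
    ordinal, down-weighting the sparse top and bottom slices.  With
    ``literal_sigma`` the Gaussian exponent divides by 2σ instead of the
    standard 2σ², for sensitivity checks against non-standard forms.
    """
    if n < 1:
        raise ValueError("need at least one slice")
    j = np.arange(1, n + 1, dtype=float)
    mu = lam * (1 + n)
    sigma = float(np.sqrt(np.mean((j - mu) ** 2)))
    if sigma == 0.0:
        w = np.ones(n) / n
    else:
        denom = 2.0 * sigma if literal_sigma else 2.0 * sigma**2
        raw = np.exp(-((j - mu) ** 2) / denom)
        w = raw / raw.sum()
    return WeightScheme(n=n, lam=lam, mu=float(mu), sigma=sigma, weights=w)


def aggregate(series: np.ndarray, operator: str, weights: WeightScheme | None = None) -> float:
    """Collapse a per-slice series to a scalar: max, mean, or weighted mean."""
    s = np.asarray(series, dtype=float)
    if s.size == 0:
        raise ValueError("cannot aggregate an empty series")
    if operator == "max":
        return float(s.max())
    if operator == "mean":
        return float(s.mean())
    if operator == "weighted":
        if weights is None:
            weights = gaussian_weights(s.size)
        if weights.n != s.size:
            raise ValueError(f"weight scheme for N={weights.n} applied to series of length {s.size}")
        return float(weights.weights @ s)
    raise ValueError(f"unknown operator {operator!r}")


def aggregation_table(
    per_strain_series: dict[str, dict[str, np.ndarray]],
    lam: float = 0.5,
    literal_sigma: bool = False,
) -> pd.DataFrame:
    """Aggregate every strain × quantity series under all three operators.

    ``per_strain_series[strain][quantity]`` is the per-slice series (mean
    over sampling points).  Returns a long-format frame with columns
    (strain, quantity, operator, value, n_slices).
    """
    rows = []
    for strain, by_q in per_strain_series.items():
        for q, series in by_q.items():
            s = np.asarray(series, dtype=float)
            ws = gaussian_weights(s.size, lam=lam, literal_sigma=literal_sigma)
            for op in OPERATORS:
                rows.append(
                    {
                        "strain": strain,
                        "quantity": q,
                        "operator": op,
                        "value": aggregate(s, op, weights=ws),
                        "n_slices": s.size,
                    }
                )
    return pd.DataFrame(rows)


def rescale_across_strains(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each (quantity, operator) column by its maximum over strains.

    After rescaling every value lies in [0, 1] and the best strain per
    column scores exactly 1, making quantities comparable across strains.
    A column whose maximum is zero (no biomass anywhere) is rejected.
    """
    out = table.copy()
    out["rescaled"] = np.nan
    for (_, _), idx in out.groupby(["quantity", "operator"]).groups.items():
        col_max = out.loc[idx, "value"].max()
        if col_max <= 0:
            raise ValueError("zero column maximum: no biomass in any strain for a quantity/operator")
        out.loc[idx, "rescaled"] = out.loc[idx, "value"] / col_max
    return out


def colonization_index(rescaled_triple: dict[str, float] | np.ndarray) -> float:
    """I_C: mean of the three rescaled quantities under one fixed operator."""
    if isinstance(rescaled_triple, dict):
        vals = np.array([rescaled_triple[q] for q in QUANTITIES], dtype=float)
    else:
        vals = np.asarray(rescaled_triple, dtype=float)
    if vals.size != 3:
        raise ValueError("colonization index needs exactly the three quantities")
    if np.any(vals < 0) or np.any(vals > 1):
        raise ValueError("rescaled quantities must lie in [0, 1]")
    return float(vals.mean())


def classify_index(ic: float) -> str:
    """Label one colonization-index value."""
    if not 0.0 <= ic <= 1.0:
        raise ValueError(f"I_C must lie in [0, 1]; got {ic}")
    if ic < POROUS_BELOW:
        return "porous"
    if ic < COMPACT_FROM:
        return "intermediate"
    return "compact"


def classify_strain(ic_per_operator: dict[str, float]) -> tuple[str, dict[str, str], bool]:
    """Strain-level architecture label from per-operator I_C values.

    Each operator's index is labelled (< 0.5 porous, ≥ 0.7 compact,
    otherwise intermediate); the strain label is the majority over
    operators.  Returns (label, per-operator labels, unanimous?).
    """
    per_op = {op: classify_index(ic) for op, ic in ic_per_operator.items()}
    labels, counts = np.unique(list(per_op.values()), return_counts=True)
    majority = str(labels[counts.argmax()])
    return majority, per_op, bool(len(labels) == 1)


def colonization_report(rescaled: pd.DataFrame) -> pd.DataFrame:
    """Per-strain I_C for every operator, plus labels and agreement flag.

    Input is the long-format rescaled table from
    :func:`rescale_across_strains`.
    """
    rows = []
    for strain, grp in rescaled.groupby("strain", sort=False):
        ic_per_op = {}
        for op in OPERATORS:
            sub = grp[grp["operator"] == op].set_index("quantity")["rescaled"]
            ic_per_op[op] = colonization_index({q: float(sub[q]) for q in QUANTITIES})
        label, per_op_labels, unanimous = classify_strain(ic_per_op)
        rows.append(
            {
                "strain": strain,
                **{f"ic_{op}": ic_per_op[op] for op in OPERATORS},
                **{f"label_{op}": per_op_labels[op] for op in OPERATORS},
                "label": label,
                "operators_agree": unanimous,
            }
        )
    return pd.DataFrame(rows)
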