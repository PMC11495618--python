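"""Session-similarity, fPCA, distinguishability and direction-bias analyses.

The headline question these analyses address is whether practice produced
*new* muscle outputs or better selection among outputs that existed from the
start.  The main tool is the 99th-percentile minimum-difference statistic:
for each session-5 trial, the minimum absolute difference between its
feature value and that of any session-1 trial, summarised per participant by
the 99th percentile of those minima — small values mean that (almost) every
session-5 output had a close session-1 counterpart.  The same comparison is
run in a three-dimensional functional-PCA feature space of the whole
channel profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from myolearn import inference

P99 = 99.0
MODE_GAP = 0.2
KDE_GRID_POINTS = 512


# ---------------------------------------------------------------------------
# 99th-percentile minimum-difference similarity

@dataclass(frozen=True)
class SimilarityEntry:
    percentile_value: float
    session5_index: int  # trial attaining (closest to) the percentile
    session1_index: int  # its nearest session-1 trial
    minima: np.ndarray   # per-session-5-trial minimum differences


def min_diff_p99(
    session5_values: np.ndarray, session1_values: np.ndarray,
    percentile: float = P99,
) -> SimilarityEntry:
    """99th percentile of per-trial minimum distances to session 1.

    Scalar features use absolute differences; vector features (e.g. fPCA
    score triples) use Euclidean distances.  The percentile uses linear
    interpolation between order statistics; the reported pair is the
    session-5 trial whose minimum is closest to the percentile value.
    """
    s5 = np.asarray(session5_values, dtype=float)
    s1 = np.asarray(session1_values, dtype=float)
    if s5.size == 0 or s1.size == 0:
        raise ValueError("both sessions must contain at least one trial")
    if s5.ndim == 1:
        s5 = s5[:, None]
    if s1.ndim == 1:
        s1 = s1[:, None]
    diffs = np.linalg.norm(s5[:, None, :] - s1[None, :, :], axis=2)
    nearest = diffs.argmin(axis=1)
    minima = diffs[np.arange(diffs.shape[0]), nearest]
    value = float(np.percentile(minima, percentile))
    i5 = int(np.argmin(np.abs(minima - value)))
    return SimilarityEntry(
        percentile_value=value,
        session5_index=i5,
        session1_index=int(nearest[i5]),
        minima=minima,
    )


def similarity_table(
    features: pd.DataFrame,
    feature_cols: dict[str, str],
    session5_conditions: list[str] | None = None,
    session_a: int = 1,
    session_b: int = 5,
) -> pd.DataFrame:
    """Per participant x channel-feature minimum-difference summary.

    Late-session (``session_b``) trials, optionally restricted to a
    condition set such as ``["R1", "R3"]``, are compared against all
    early-session (``session_a``) trials of any condition.
    ``feature_cols`` maps an output label, e.g. ``"hand_amplitude"``, to a
    column of the tidy feature table.
    """
    rows = []
    cond = features["direction"].astype(str) + features["magnitude"].astype(str)
    for pid, grp in features.groupby("participant"):
        gcond = cond.loc[grp.index]
        s1 = grp[grp["session"] == session_a]
        s5 = grp[grp["session"] == session_b]
        if session5_conditions is not None:
            s5 = s5[gcond.loc[s5.index].isin(session5_conditions)]
        for label, col in feature_cols.items():
            a5 = s5[col].dropna().to_numpy()
            a1 = s1[col].dropna().to_numpy()
            if a5.size == 0 or a1.size == 0:
                continue
            entry = min_diff_p99(a5, a1)
            rows.append({
                "participant": pid,
                "feature": label,
                "p99_min_diff": entry.percentile_value,
                "n_session5": a5.size,
                "n_session1": a1.size,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# functional PCA of channel profiles

@dataclass(frozen=True)
class FPCABasis:
    mean: np.ndarray                 # (T,)
    components: np.ndarray           # (k, T), orthonormal on the grid
    explained_variance: np.ndarray   # (k,) fractions, non-increasing
    grid: np.ndarray                 # common time grid (seconds)

    @property
    def cumulative_explained(self) -> float:
        return float(self.explained_variance.sum())


def fit_fpca(profiles: np.ndarray, grid: np.ndarray, k: int = 3) -> FPCABasis:
    """Top-k functional principal components of profiles on a common grid.

    Plain discretised covariance eigen-decomposition (via SVD of the
    mean-centred data matrix); components are orthonormal with respect to
    the Euclidean inner product on the grid.
    """
    x = np.asarray(profiles, dtype=float)
    if x.ndim != 2:
        raise ValueError("profiles must be a (n, T) matrix")
    n = x.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} profiles, got {n}")
    mean = x.mean(axis=0)
    centred = x - mean
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    total = float((svals**2).sum())
    if total == 0.0:
        raise ValueError("profiles have zero variance (all identical)")
    explained = svals[:k] ** 2 / total
    return FPCABasis(
        mean=mean,
        components=vt[:k],
        explained_variance=explained,
        grid=np.asarray(grid, dtype=float),
    )


def project_fpca(profile: np.ndarray, basis: FPCABasis) -> np.ndarray:
    """Score vector of a profile: inner products with the components after
    mean subtraction."""
    p = np.asarray(profile, dtype=float)
    if p.shape[-1] != basis.mean.size:
        raise ValueError("profile is not on the basis grid")
    return (p - basis.mean) @ basis.components.T


# ---------------------------------------------------------------------------
# KDE-mode distinguishability of the three rightward conditions

@dataclass(frozen=True)
class DistinguishabilityResult:
    participant: str
    modes: dict        # (channel, magnitude) -> modal peak amplitude
    label: str         # "distinguishable" | "indistinguishable"


def kde_mode(samples: np.ndarray, grid_points: int = KDE_GRID_POINTS) -> float:
    """Mode of a Gaussian KDE (Silverman bandwidth) on a fixed grid
    spanning the data range plus three bandwidths."""
    x = np.asarray(samples, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 samples for a KDE mode")
    if np.ptp(x) == 0:
        return float(x[0])
    kde = stats.gaussian_kde(x, bw_method="silverman")
    bw = float(np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, grid_points)
    return float(grid[np.argmax(kde(grid))])


def distinguishability_group(
    participant: str,
    amplitudes: dict[tuple[str, int], np.ndarray],
    gap: float = MODE_GAP,
) -> DistinguishabilityResult:
    """Group a participant by whether any channel's modal peak amplitudes
    for R1, R2 and R3 are all pairwise more than ``gap`` apart."""
    modes = {key: kde_mode(vals) for key, vals in amplitudes.items()}
    channels = sorted({ch for ch, _ in modes})
    distinguishable = False
    for ch in channels:
        ms = sorted(modes[(ch, m)] for m in (1, 2, 3) if (ch, m) in modes)
        if len(ms) < 3:
            continue
        gaps = np.diff(ms)
        if np.all(gaps > gap):
            distinguishable = True
    return DistinguishabilityResult(
        participant=participant,
        modes=modes,
        label="distinguishable" if distinguishable else "indistinguishable",
    )


# ---------------------------------------------------------------------------
# direction-bias contrasts

@dataclass(frozen=True)
class DirectionBias:
    participant: str
    magnitude: int
    feature: str
    difference_draws: np.ndarray  # rightward minus leftward, per draw
    ci95: tuple[float, float]


def direction_bias(
    features: pd.DataFrame,
    magnitude: int,
    feature: str = "epsilon",
    config: inference.SamplerConfig | None = None,
    day: int = 1,
) -> list[DirectionBias]:
    """Posterior of (rightward − leftward) mean feature per participant.

    Order-correct no-feedback trials of one magnitude are pooled across the
    two directions, standardised jointly, and a per-cell normal model is
    fitted with direction in the scale slot; the reported contrast is the
    per-participant difference of the two direction means.
    """
    sel = features[
        (features["magnitude"] == magnitude)
        & (features["session"] == day)
    ].copy()
    for d in ("R", "L"):
        if not (sel["direction"] == d).any():
            raise ValueError(f"no trials for direction {d!r}")
    sel["scale"] = sel["direction"]
    sel["day"] = day
    post = inference.fit_channel_feature_model(sel, feature, config)
    out = []
    for pid in sorted(sel["participant"].unique()):
        try:
            right = post.cell_mu(pid, "R", day)
            left = post.cell_mu(pid, "L", day)
        except KeyError:
            continue
        diff = right - left
        lo, hi = np.percentile(diff, [2.5, 97.5])
        out.append(DirectionBias(
            participant=pid,
            magnitude=magnitude,
            feature=feature,
            difference_draws=diff,
            ci95=(float(lo), float(hi)),
        ))
    return out
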