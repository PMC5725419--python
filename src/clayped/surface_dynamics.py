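"""Mobility of adsorbed species: lateral drift velocities, preferred
diffusion directions with a six-fold-symmetry test, and post-first-binding
residence statistics.

The C-terminal carbon of every molecule is tracked; for each pair of
consecutive frames in which a molecule is adsorbed in both, the xy
displacement (periodic minimum image) yields a drift velocity in Angstrom/ns
and a polar direction in [0, 360) deg.  Lattice-templated diffusion along the
hexagonal metal sublattice shows up as 60-deg-periodic peaks in the circular
autocorrelation of the direction histogram; a seeded Monte-Carlo null
(uniform directions, same sample size) turns the peak contrast into a
p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .adsorption_templating import AdsorptionSeries
from .io import Trajectory, minimum_image

__all__ = [
    "DiffusionStats",
    "SixFoldResult",
    "ResidenceStats",
    "track_velocities",
    "direction_autocorrelation",
    "six_fold_score",
    "residence",
]

# lags carrying six-fold information; 180 deg is shared by any
# inversion-symmetric histogram and 90/270 by four-fold patterns, so all
# three are excluded from both the peak set and the off-peak baseline.
_PEAK_LAGS = np.array([60, 120, 240, 300])
_EXCLUDED_LAGS = {0, 90, 180, 270}


@dataclass
class DiffusionStats:
    """Per-step drift of adsorbed C-terminal carbons.

    ``velocities`` (Angstrom/ns) and ``directions`` (deg, [0, 360)) cover
    every qualifying step (molecule adsorbed in both frames of the pair);
    ``histogram`` bins directions at 1 deg.
    """

    velocities: np.ndarray
    directions: np.ndarray
    histogram: np.ndarray

    @property
    def n_steps(self) -> int:
        return len(self.velocities)


@dataclass
class SixFoldResult:
    """Circular autocorrelation of the direction histogram and its six-fold score.

    ``autocorrelation[lag]`` for lags 0..359 deg, mean-subtracted counts
    normalized by the lag-0 value; ``score`` is the mean autocorrelation at
    the six-fold lags minus the off-peak mean; ``p_value`` is the fraction of
    seeded uniform-direction resamples whose score reaches the observed one
    (None when no null was computed).
    """

    autocorrelation: np.ndarray | None
    score: float | None
    p_value: float | None
    null_scores: np.ndarray | None = None


@dataclass
class ResidenceStats:
    """Fraction of frames spent adsorbed after the first adsorption event."""

    per_molecule: np.ndarray  # NaN for molecules never adsorbed
    mean: float
    std: float
    n_never_adsorbed: int


def track_velocities(
    traj: Trajectory, adsorption: AdsorptionSeries
) -> DiffusionStats:
    """Drift velocity and polar direction for every qualifying step.

    A step qualifies when the molecule is adsorbed (via its C-terminus) in
    two consecutive frames; the xy displacement is unwrapped by minimum image
    before differencing.  Single-frame trajectories yield an empty result
    with a warning.
    """
    nf = traj.n_frames
    if nf < 2:
        warnings.warn("trajectory has fewer than two frames; no diffusion steps")
        return DiffusionStats(np.empty(0), np.empty(0), np.zeros(360, dtype=int))
    dt = np.diff(traj.times)
    if np.any(dt <= 0):
        raise ValueError("frame times must be strictly increasing")
    ct_rows = np.array([m.ct for m in adsorption.molecules])
    vels, dirs = [], []
    for f in range(nf - 1):
        both = adsorption.backbone[f] & adsorption.backbone[f + 1]
        if not both.any():
            continue
        rows = ct_rows[both]
        d = traj.coords[f + 1][rows, :2] - traj.coords[f][rows, :2]
        d = minimum_image(d, traj.box[f][:2])
        r = np.sqrt((d**2).sum(axis=1))
        vels.append(r / dt[f])
        # microdegree rounding keeps exact lattice steps in their nominal bin
        deg = np.round(np.degrees(np.arctan2(d[:, 1], d[:, 0])), 6)
        dirs.append(deg % 360.0)
    if vels:
        velocities = np.concatenate(vels)
        directions = np.concatenate(dirs)
    else:
        velocities = np.empty(0)
        directions = np.empty(0)
    hist = np.histogram(directions, bins=np.arange(361.0))[0]
    return DiffusionStats(velocities, directions, hist)


def _circular_autocorr(hist: np.ndarray) -> np.ndarray:
    h = hist.astype(float) - hist.mean()
    # wrap-around correlation via FFT; normalize by the lag-0 value
    f = np.fft.rfft(h)
    ac = np.fft.irfft(f * np.conj(f), n=len(h))
    if ac[0] <= 0:
        return np.zeros_like(ac)
    return ac / ac[0]


def six_fold_score(autocorr: np.ndarray) -> float:
    """Mean autocorrelation at the six-fold lags minus the off-peak mean."""
    lags = np.arange(len(autocorr))
    peaks = autocorr[_PEAK_LAGS]
    off = np.array(
        [autocorr[l] for l in lags if l % 60 != 0 and l not in _EXCLUDED_LAGS]
    )
    return float(peaks.mean() - off.mean())


def direction_autocorrelation(
    stats: DiffusionStats,
    n_permutations: int = 1000,
    rng_seed: int = 0,
) -> SixFoldResult:
    """Circular autocorrelation of the direction histogram plus six-fold test.

    Returns an explicit null result when there are no qualifying steps.  The
    significance null redraws the same number of directions uniformly on
    [0, 360) ``n_permutations`` times (seeded) and reports the fraction of
    resamples with a score at least as large as the observed one.
    """
    if stats.n_steps == 0:
        return SixFoldResult(None, None, None)
    ac = _circular_autocorr(stats.histogram)
    score = six_fold_score(ac)
    p_value = None
    null_scores = None
    if n_permutations > 0:
        rng = np.random.default_rng(rng_seed)
        null_scores = np.empty(n_permutations)
        for i in range(n_permutations):
            sample = rng.uniform(0.0, 360.0, size=stats.n_steps)
            h = np.histogram(sample, bins=np.arange(361.0))[0]
            null_scores[i] = six_fold_score(_circular_autocorr(h))
        p_value = float((1 + np.sum(null_scores >= score)) / (1 + n_permutations))
    return SixFoldResult(ac, score, p_value, null_scores)


def residence(traj: Trajectory, adsorption: AdsorptionSeries) -> ResidenceStats:
    """Per-molecule fraction of frames adsorbed after the first binding event.

    The first adsorbed frame is included in the window; molecules never
    adsorbed are excluded from the population statistics and counted
    separately.
    """
    if adsorption.backbone.shape[0] != traj.n_frames:
        raise ValueError("adsorption series not aligned with trajectory")
    bb = adsorption.backbone
    n_mol = bb.shape[1]
    fractions = np.full(n_mol, np.nan)
    for m in range(n_mol):
        hits = np.flatnonzero(bb[:, m])
        if hits.size == 0:
            continue
        f0 = hits[0]
        fractions[m] = bb[f0:, m].mean()
    valid = fractions[~np.isnan(fractions)]
    return ResidenceStats(
        fractions,
        float(valid.mean()) if valid.size else float("nan"),
        float(valid.std()) if valid.size else float("nan"),
        int(np.isnan(fractions).sum()),
    )
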