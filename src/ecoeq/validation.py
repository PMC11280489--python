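"""Quantifying equalization benefit: percentage errors, summaries, paired tests.

The benefit of equalizing a recorder is measured against the reference
sound-level meter in two ways:

* the amplitude RMSE between the two dB spectra (see
  :func:`ecoeq.spectral.amplitude_rmse`), and
* the signed fractional error of each eco-acoustic index,
  ``(Index_slm − Index_recorder) / Index_slm``, reported in percent, with
  a per-recording *total* equal to the sum of the eight absolute errors.

Whether index series from simultaneous recordings differ significantly is
decided by an assumption-gated paired test: Shapiro–Wilk normality on
each series and Bartlett homoscedasticity across the two select between
the paired Student t-test and the paired Wilcoxon signed-rank test, at
α = 0.05.  H0 (zero mean difference) is retained iff p > α.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .audio_io import AudioSegment
from .equalizer import compute_curve, equalize
from .indices import IndexConfig, IndexResult, compute_all
from .spectral import amplitude_rmse, estimate_psd
from .synthetic import (
    DeviceProfile,
    canonical_profiles,
    generate_scene,
    generate_white_noise,
    simulate_device,
)

__all__ = [
    "PairedTestResult",
    "RecordingComparison",
    "ValidationReport",
    "percentage_error",
    "index_errors",
    "paired_compare",
    "summarize",
    "run_synthetic_battery",
]

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


def percentage_error(index_ref: float, index_dev: float) -> float:
    """Signed fractional index error, reference in the numerator's favor.

    ``(ref − dev) / ref``; multiply by 100 when formatting as percent.  A
    zero reference makes the error undefined: NaN is returned with a
    warning and such entries are excluded from totals.
    """
    if index_ref == 0:
        log.warning("percentage error undefined for zero reference index")
        return float("nan")
    return (index_ref - index_dev) / index_ref


def index_errors(ref: IndexResult, dev: IndexResult) -> dict[str, float]:
    """Per-index fractional errors between two recordings' index sets."""
    return {
        name: percentage_error(getattr(ref, name), getattr(dev, name))
        for name in IndexResult.INDEX_NAMES
    }


class PairedTestResult(NamedTuple):
    """Outcome of the assumption-gated paired comparison."""

    test_name: str  # "paired-t", "paired-wilcoxon" or "degenerate"
    p_value: float
    h0_retained: bool
    degenerate: bool = False


def paired_compare(
    ref_series: Sequence[float],
    dev_series: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
) -> PairedTestResult:
    """Paired test of zero mean difference with a normality/variance gate.

    Shapiro–Wilk is run on each series and Bartlett across the two; only
    if all three pass at ``alpha`` is the paired Student t-test used,
    otherwise the paired Wilcoxon signed-rank test.  Identical series
    (all differences zero) are degenerate: H0 is retained with p = 1 and
    the result flagged.
    """
    ref = np.asarray(ref_series, dtype=np.float64)
    dev = np.asarray(dev_series, dtype=np.float64)
    if ref.shape != dev.shape or ref.ndim != 1:
        raise ValueError("series must be 1-D and of equal length (paired)")
    if ref.size < 3:
        raise ValueError(f"need at least 3 pairs, got {ref.size}")
    diffs = dev - ref
    if np.all(diffs == 0):
        return PairedTestResult("degenerate", 1.0, True, degenerate=True)

    def _safe_shapiro(x: np.ndarray) -> float:
        if np.ptp(x) == 0:  # constant series: maximally non-normal
            return 0.0
        return float(stats.shapiro(x).pvalue)

    gate_ok = (
        _safe_shapiro(ref) > alpha
        and _safe_shapiro(dev) > alpha
        and (np.ptp(ref) > 0 and np.ptp(dev) > 0)
        and float(stats.bartlett(ref, dev).pvalue) > alpha
    )
    if gate_ok:
        p = float(stats.ttest_rel(ref, dev).pvalue)
        name = "paired-t"
    else:
        p = float(stats.wilcoxon(ref, dev).pvalue)
        name = "paired-wilcoxon"
    return PairedTestResult(name, p, h0_retained=p > alpha)


@dataclass(frozen=True)
class RecordingComparison:
    """One recording's device-vs-reference comparison.

    ``status`` distinguishes the unequalized recording ("original") from
    equalized ones ("eq512", "eq1024", "eq16384"); ``index_errors`` holds
    signed fractional errors keyed by index name.
    """

    device: str
    status: str
    amplitude_rmse_db: float
    index_errors: dict[str, float]

    @property
    def total_abs_error(self) -> float:
        """Sum of the absolute index errors (NaN entries excluded)."""
        vals = np.asarray(list(self.index_errors.values()), dtype=np.float64)
        return float(np.nansum(np.abs(vals)))


@dataclass(frozen=True)
class ValidationReport:
    """Aggregated per-(device, status) summary plus optional test table."""

    summary: pd.DataFrame
    tests: pd.DataFrame | None = None
    alpha: float = DEFAULT_ALPHA

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.summary.to_csv(path, index=False)
        if self.tests is not None:
            self.tests.to_csv(path.with_suffix(".tests.csv"), index=False)
        return path


def summarize(
    comparisons: Sequence[RecordingComparison],
    tests: pd.DataFrame | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> ValidationReport:
    """Aggregate per-recording comparisons per (device, status).

    Emits, per device and status, the mean amplitude RMSE, the median of
    each index's signed percentage error across recordings, and the total
    percentage error — the mean over recordings of the per-recording sums
    of absolute index errors (totals use magnitudes: individual errors
    may cancel in sign while both recordings are biased).
    """
    if not comparisons:
        raise ValueError("no comparisons to summarize")
    rows = []
    for c in comparisons:
        row = {
            "device": c.device,
            "status": c.status,
            "amplitude_rmse_db": c.amplitude_rmse_db,
            "total_abs_error_pct": 100.0 * c.total_abs_error,
        }
        row.update({f"err_{k}_pct": 100.0 * v for k, v in c.index_errors.items()})
        rows.append(row)
    per_rec = pd.DataFrame(rows)
    err_cols = [c for c in per_rec.columns if c.startswith("err_")]
    agg = {"amplitude_rmse_db": "mean", "total_abs_error_pct": "mean"}
    agg.update({c: "median" for c in err_cols})
    summary = (
        per_rec.groupby(["device", "status"], sort=True).agg(agg).reset_index()
    )
    return ValidationReport(summary=summary, tests=tests, alpha=alpha)


def run_synthetic_battery(
    profiles: Sequence[DeviceProfile] | None = None,
    orders: Sequence[int] = (1024,),
    seed: int = 0,
    n_scenes: int = 3,
    scene_duration: float = 60.0,
    config: IndexConfig | None = None,
    rmse_fmin: float = 500.0,
    rmse_fmax: float = 15000.0,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[list[RecordingComparison], ValidationReport]:
    """End-to-end in-silico validation of the equalization protocol.

    For each device profile: derive equalization curves from a paired
    white-noise take (the reference meter's take is the stimulus itself;
    the reference gain applied before the ratio equals the profile's own
    gain, compensating the deployed amplifier setting exactly), color a
    set of synthetic scenes through the profile, equalize them at every
    requested order, and compare original and equalized recordings to the
    reference scene: amplitude RMSE on [rmse_fmin, rmse_fmax] plus the
    eight index percentage errors.  All recordings entering the index
    comparison are truncated to a common duration — the original length
    minus half the largest order — so every status sees the same window.

    Returns the per-recording comparisons and the aggregated report
    (including assumption-gated paired tests per device/status/index when
    at least three scenes are available).
    """
    profiles = list(profiles) if profiles is not None else list(canonical_profiles().values())
    orders = sorted(set(int(o) for o in orders))
    cfg = config or IndexConfig()
    children = np.random.SeedSequence(seed).spawn(1 + n_scenes)
    stim_seed = int(children[0].generate_state(1)[0] % 2**31)
    scene_seeds = [int(c.generate_state(1)[0] % 2**31) for c in children[1:]]

    stimulus = generate_white_noise(seed=stim_seed)
    scenes = [
        generate_scene(duration=scene_duration, seed=s) for s in scene_seeds
    ]
    max_half = max(orders) // 2
    m = len(scenes[0]) - max_half

    def _truncate(seg: AudioSegment) -> AudioSegment:
        return seg.with_samples(seg.samples[:m])

    refs = [_truncate(s) for s in scenes]
    ref_specs = [estimate_psd(r, nfft=cfg.nfft) for r in refs]
    ref_indices = [compute_all(r, cfg) for r in refs]

    comparisons: list[RecordingComparison] = []
    series: dict[tuple[str, str, str], list[float]] = {}

    for profile in profiles:
        dev_noise = simulate_device(stimulus, profile)
        curves = {
            order: compute_curve(
                stimulus, dev_noise, order, ref_gain_db=profile.gain_db
            )
            for order in orders
        }
        for i, scene in enumerate(scenes):
            dev_scene = simulate_device(scene, profile)
            takes = {"original": _truncate(dev_scene)}
            for order in orders:
                takes[f"eq{order}"] = _truncate(equalize(dev_scene, curves[order]))
            for status, take in takes.items():
                rmse = amplitude_rmse(
                    ref_specs[i],
                    estimate_psd(take, nfft=cfg.nfft),
                    fmin=rmse_fmin,
                    fmax=rmse_fmax,
                )
                dev_idx = compute_all(take, cfg)
                errs = index_errors(ref_indices[i], dev_idx)
                comparisons.append(
                    RecordingComparison(profile.name, status, rmse, errs)
                )
                for name in IndexResult.INDEX_NAMES:
                    series.setdefault((profile.name, status, name), []).append(
                        getattr(dev_idx, name)
                    )

    tests = None
    if n_scenes >= 3:
        rows = []
        for (device, status, name), dev_vals in sorted(series.items()):
            ref_vals = [getattr(r, name) for r in ref_indices]
            result = paired_compare(ref_vals, dev_vals, alpha=alpha)
            rows.append(
                {
                    "device": device,
                    "status": status,
                    "index": name,
                    "test": result.test_name,
                    "p_value": result.p_value,
                    "h0_retained": result.h0_retained,
                }
            )
        tests = pd.DataFrame(rows)
    return comparisons, summarize(comparisons, tests=tests, alpha=alpha)
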