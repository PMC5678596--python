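"""Ground-truth validation benchmarks for the segmentation/trait pipeline.

Each function builds a fully synthetic input (or an enumerable one), runs the
relevant part of the pipeline, and measures its accuracy against an
independent reference — exhaustive search for the Otsu threshold, rasterised
ground-truth masks and areas for the generator scenes, closed-form rates for
RER.  They are the desk-scale analogue of validating area estimates against
destructive leaf measurements: the numbers they return are measured at call
time, never stored.

All randomness is controlled by the ``seed`` arguments.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .chanvese import ChanVeseParams, average_passes, chan_vese, propagate_dark_period
from .growth import PRASeries, daily_rer, rer
from .illumination import IlluminationParams, correct_illumination
from .labeling import PlantSeed, label_seeded
from .metrics import dice, mape
from .pipeline import PipelineSettings, _areas_frame, _segment_vis, run_on_session
from .session import build_session
from .synthetic import SceneSpec, generate_session
from .threshold import otsu_threshold

__all__ = [
    "otsu_bruteforce",
    "otsu_oracle_agreement",
    "disk_recovery",
    "dark_period_fidelity",
    "rer_recovery",
    "dawn_dip_reproduction",
    "forward_reverse_consistency",
    "illumination_benchmark",
]


def otsu_bruteforce(gray: np.ndarray) -> int:
    """Reference Otsu threshold by plain exhaustive search over all 256 cuts.

    Deliberately naive (per-threshold recomputation) so it shares no code
    with :func:`phenodiel.threshold.otsu_threshold`.
    """
    flat = np.asarray(gray).ravel().astype(np.float64)
    best_t, best_v = None, -1.0
    for t in range(256):
        lo = flat[flat <= t]
        hi = flat[flat > t]
        if lo.size == 0 or hi.size == 0:
            continue
        v = lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-9:
            best_v, best_t = v, t
    if best_t is None:
        raise ValueError("degenerate histogram")
    return best_t


def otsu_oracle_agreement(
    n_images: int = 100, size: int = 16, seed: int = 0
) -> dict:
    """Fraction of random 8-bit images where the fast Otsu matches brute force."""
    rng = np.random.default_rng(seed)
    n_match = 0
    for _ in range(n_images):
        img = rng.integers(0, 256, (size, size), dtype=np.uint8)
        t_fast, _ = otsu_threshold(img)
        if t_fast == otsu_bruteforce(img):
            n_match += 1
    return {
        "n_images": n_images,
        "n_match": n_match,
        "agreement_pct": 100.0 * n_match / n_images,
    }


def disk_recovery(n_cases: int = 20, seed: int = 0) -> dict:
    """Chan-Vese on piecewise-constant disks with perturbed initialisations.

    Each case draws a disk (radius 14–22 px, foreground/background levels
    with strong contrast) and initialises the contour with the true disk
    dilated or eroded by 5 px; reports the minimum converged Dice against the
    true disk and whether the energy decreased monotonically in every run.
    """
    rng = np.random.default_rng(seed)
    min_dice, all_monotone = 1.0, True
    for case in range(n_cases):
        h = w = 96
        yy, xx = np.indices((h, w))
        r = int(rng.integers(14, 23))
        cy, cx = (int(rng.integers(r + 8, s - r - 8)) for s in (h, w))
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 < r**2
        fg = int(rng.integers(170, 231))
        bg = int(rng.integers(30, 91))
        img = np.where(disk, fg, bg).astype(np.uint8)
        op = ndimage.binary_dilation if case % 2 == 0 else ndimage.binary_erosion
        init = op(disk, iterations=5)
        mask, state = chan_vese(img, init)
        min_dice = min(min_dice, dice(mask, disk))
        all_monotone &= bool(
            (np.diff(state.energy_history) <= 1e-9).all()
        )
    return {"n_cases": n_cases, "min_dice": min_dice, "all_monotone": all_monotone}


def _centre_seeds(spec: SceneSpec) -> list[PlantSeed]:
    rows, cols = spec.grid
    return [
        PlantSeed(k + 1,
                  (k % cols) * spec.cell_px + spec.cell_px / 2,
                  (k // cols) * spec.cell_px + spec.cell_px / 2)
        for k in range(spec.n_plants)
    ]


def _propagate_both(session, truth, settings: PipelineSettings):
    """Forward + reverse propagation through the first full dark period,
    seeded from the pipeline's own VIS segmentations of the adjacent light
    frames, with identities anchored to the tray layout."""
    spec = truth.spec
    dark = session.dark_periods()[0]
    seeds = _centre_seeds(spec)
    seed_f = label_seeded(
        _segment_vis(session.frames[dark.start - 1], settings), seeds
    )
    seed_r = label_seeded(
        _segment_vis(session.frames[dark.stop], settings), seeds
    )
    frames = session.period_frames(dark)
    fwd = propagate_dark_period(
        frames, seed_f, "forward", settings.chanvese, settings.illumination
    )
    rev = propagate_dark_period(
        frames[::-1], seed_r, "reverse", settings.chanvese, settings.illumination
    )[::-1]
    idx = list(range(dark.start, dark.stop))
    return dark, idx, seed_f.plant_ids, fwd, rev


def dark_period_fidelity(seed: int = 0, grid: tuple[int, int] = (2, 3)) -> dict:
    """Propagated dark-period PRA vs generator ground truth.

    One full dark period at the generator's default noise and radial falloff,
    illumination correction on; the forward and reverse passes are averaged.
    Returns the per-plant-pooled MAPE (%) and the worst per-frame Dice of
    either pass.
    """
    spec = SceneSpec.wt_like(grid=grid, duration_hours=26.0, rng_seed=seed)
    session, truth = generate_session(spec)
    settings = PipelineSettings(calibration=spec.calibration)
    dark, idx, pids, fwd, rev = _propagate_both(session, truth, settings)
    est = average_passes(
        _areas_frame(fwd, idx, pids), _areas_frame(rev, idx, pids)
    )
    tru = truth.areas_px.loc[idx, list(pids)].to_numpy(float)
    min_frame_dice = min(
        dice(m.labels > 0, truth.masks[i].labels > 0)
        for masks in (fwd, rev)
        for i, m in zip(idx, masks)
    )
    return {
        "n_frames": len(idx),
        "n_plants": len(pids),
        "mape_pct": mape(est.to_numpy(), tru),
        "min_frame_dice": min_frame_dice,
    }


def rer_recovery(seed: int = 0, r_true: float = 0.15, n_days: int = 3) -> dict:
    """Daily RER on constructed exponential PRA series, 20-min sampling.

    Noiseless series must return the generating rate to machine precision;
    with 2% multiplicative noise the per-plant mean over ``n_days`` must stay
    near the true rate.  Returns the worst absolute error (noiseless) and the
    worst relative error in percent (noisy, over 6 plants).
    """
    from .session import Frame, Modality, PhotoperiodSchedule
    import datetime as dt

    schedule = PhotoperiodSchedule(dt.time(8, 0), dt.time(20, 0))
    start = dt.datetime(2024, 3, 1, 8, 0)
    n = n_days * 72
    times = [start + dt.timedelta(minutes=20 * k) for k in range(n)]
    t_days = np.arange(n) * 20 / 1440.0
    blank_vis = np.zeros((4, 4, 3), np.uint8)
    blank_nir = np.zeros((4, 4), np.uint8)
    frames = [
        Frame(
            blank_vis if schedule.is_light(ts) else blank_nir,
            ts,
            Modality.VIS if schedule.is_light(ts) else Modality.NIR,
        )
        for ts in times
    ]
    session = build_session(frames, schedule)

    base = 100.0 * np.exp(r_true * t_days)
    clean = PRASeries(1, t_days, base, frame_index=np.arange(n))
    daily_clean = [v for _, v in daily_rer(clean, session)]
    noiseless_err = max(abs(v - r_true) for v in daily_clean)

    rng = np.random.default_rng(seed)
    noisy_rel_err = 0.0
    for pid in range(6):
        noisy = base * rng.normal(1.0, 0.02, n)
        series = PRASeries(pid + 1, t_days, noisy, frame_index=np.arange(n))
        vals = [v for _, v in daily_rer(series, session)]
        rel = abs(float(np.mean(vals)) - r_true) / r_true
        noisy_rel_err = max(noisy_rel_err, rel)
    return {
        "n_days": n_days,
        "r_true": r_true,
        "noiseless_max_abs_err": noiseless_err,
        "noisy_max_rel_err_pct": 100.0 * noisy_rel_err,
    }


def dawn_dip_reproduction(seed: int = 0, grid: tuple[int, int] = (2, 2)) -> dict:
    """End-to-end diel-pattern check: the dip-bearing preset must show a PRA
    local minimum within 2 h after lights-on at (most) dawns; the dip-free
    preset must show none.  Three simulated dawns per run."""
    out = {}
    for name, spec in (
        ("wt", SceneSpec.wt_like(grid=grid, duration_hours=74.0, rng_seed=seed)),
        ("mutant", SceneSpec.mutant_like(grid=grid, duration_hours=74.0,
                                         rng_seed=seed)),
    ):
        session, truth = generate_session(spec)
        result = run_on_session(
            session, PipelineSettings(calibration=spec.calibration)
        )
        per_plant = [
            sum(d["dipped"] for d in dips) for dips in result.dawn_dips.values()
        ]
        n_dawns = max(len(d) for d in result.dawn_dips.values())
        out[f"{name}_min_dips"] = min(per_plant)
        out[f"{name}_max_dips"] = max(per_plant)
        out["n_dawns"] = n_dawns
    return out


def forward_reverse_consistency(seed: int = 0) -> dict:
    """Forward vs reverse propagation on a time-symmetric (static) scene.

    With zero growth and no dawn dip the dark period is statistically
    identical in both directions, so the two passes must agree frame by
    frame; the averaged series must lie between them everywhere.
    """
    spec = SceneSpec(
        grid=(2, 2), duration_hours=26.0, r_per_day=(0.0, 0.0),
        dip_amplitude=0.0, rng_seed=seed,
    )
    session, truth = generate_session(spec)
    settings = PipelineSettings(calibration=spec.calibration)
    dark, idx, pids, fwd, rev = _propagate_both(session, truth, settings)
    f = _areas_frame(fwd, idx, pids)
    r = _areas_frame(rev, idx, pids)
    diff_pct = (np.abs(f - r) / ((f + r) / 2.0) * 100.0).to_numpy()
    avg = average_passes(f, r)
    bounded = bool(
        ((avg >= np.minimum(f, r) - 1e-9) & (avg <= np.maximum(f, r) + 1e-9))
        .to_numpy()
        .all()
    )
    return {
        "n_frames": len(idx),
        "max_frame_diff_pct": float(np.nanmax(diff_pct)),
        "average_bounded": bounded,
    }


def illumination_benchmark(n_scenes: int = 10, seed: int = 0) -> dict:
    """Correction on flat scenes with a +-40 grey-level linear gradient.

    Bright disks stand in for rosettes and, like the plants in a tray, never
    touch or overlap.  Measures the background standard-deviation reduction
    and whether Otsu segmentation of the disks ever gets worse after
    correction.
    """
    min_reduction = np.inf
    n_regressions = 0
    for k in range(n_scenes):
        rng = np.random.default_rng([seed, k])
        h, w = 120, 160
        yy, xx = np.indices((h, w))
        grad = 80.0 * xx / (w - 1) - 40.0
        disks = np.zeros((h, w), bool)
        centres: list[tuple[int, int]] = []
        while len(centres) < 4:
            cy = int(rng.integers(20, h - 20))
            cx = int(rng.integers(20, w - 20))
            if all(np.hypot(cy - y0, cx - x0) >= 28 for y0, x0 in centres):
                centres.append((cy, cx))
        for cy, cx in centres:
            disks |= (yy - cy) ** 2 + (xx - cx) ** 2 < 12**2
        img = np.where(disks, 205.0, 120.0) + grad + rng.normal(0, 3, (h, w))
        img = np.clip(np.round(img), 0, 255).astype(np.uint8)
        corr = correct_illumination(img)
        bg = ~disks
        reduction = 1.0 - np.std(corr[bg].astype(float)) / np.std(
            img[bg].astype(float)
        )
        min_reduction = min(min_reduction, reduction)
        _, m0 = otsu_threshold(img)
        _, m1 = otsu_threshold(corr)
        if dice(m1, disks) < dice(m0, disks):
            n_regressions += 1
    return {
        "n_scenes": n_scenes,
        "min_std_reduction_pct": 100.0 * float(min_reduction),
        "n_dice_regressions": n_regressions,
    }
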