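"""Two-region Chan-Vese active contour and dark-period mask propagation.

The Chan-Vese model segments an image into foreground and background regions,
each summarised by its mean intensity, by minimising

    E = mu * |boundary|  +  lambda_in  * sum_in  (I - c_in)^2
                         +  lambda_out * sum_out (I - c_out)^2

where ``c_in``/``c_out`` are the region means (recomputed each iteration) and
``|boundary|`` counts 4-adjacent pixel pairs with different labels.

The minimisation here is level-set-free: a checkerboard pixel-flip sweep over
the narrow band around the current contour.  Flips within one checkerboard
colour never share a lattice edge, so their exact energy changes (data term
plus incremental perimeter) are additive and the scheme is guaranteed to
decrease the energy monotonically — region means are then re-estimated, which
can only decrease it further.

Dark-period (NIR) frames are segmented by evolving each plant's mask
independently, seeded from the adjacent light-period VIS mask and propagated
frame to frame.  Forward passes (chronological, seeded from the last VIS image
of the preceding light period) bias the contour to expand; reverse passes
(anti-chronological, seeded from the first VIS image of the following light
period) bias it to contract.  Both directions can be averaged per frame.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .illumination import IlluminationParams, correct_illumination
from .labeling import LabeledMask
from .session import Frame

__all__ = [
    "Direction",
    "ChanVeseParams",
    "ContourState",
    "chan_vese",
    "chan_vese_energy",
    "propagate_dark_period",
    "average_passes",
]

#: lambda_out / lambda_in ratio implementing the expansion bias
EXPAND_RATIO = 2.0


class Direction(str, enum.Enum):
    EXPAND = "expand"
    CONTRACT = "contract"
    FREE = "free"


@dataclass(frozen=True)
class ChanVeseParams:
    """Contour-evolution weights and stopping rule.

    mu: boundary-length penalty (intensities normalised to [0, 1]).  With the
    discrete 4-neighbour perimeter, advancing a flat contour front costs
    2*mu per pixel, so mu must stay below half the squared region contrast
    or the front pins; the default 0.05 leaves headroom at NIR contrasts;
    lambda_in/lambda_out: region data weights (direction presets override);
    tol: stop when the fraction of pixels changing label in an iteration
    drops below this; direction: expand / contract / free bias.
    """

    mu: float = 0.05
    lambda_in: float = 1.0
    lambda_out: float = 1.0
    max_iters: int = 200
    tol: float = 1e-4
    direction: Direction = Direction.FREE

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.lambda_in <= 0 or self.lambda_out <= 0:
            raise ValueError("lambda weights must be > 0")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.tol < 0:
            raise ValueError("tol must be >= 0")

    def effective_lambdas(self) -> tuple[float, float]:
        """(lambda_in, lambda_out) after applying the direction bias.

        Expansion penalises the outside region more (lambda_out/lambda_in =
        2 by default), so growth into plausible pixels is cheap and shrinking
        is discouraged; contraction is the mirror image.
        """
        if self.direction is Direction.EXPAND:
            return self.lambda_in, self.lambda_in * EXPAND_RATIO
        if self.direction is Direction.CONTRACT:
            return self.lambda_out * EXPAND_RATIO, self.lambda_out
        return self.lambda_in, self.lambda_out


@dataclass
class ContourState:
    """Converged contour summary: mask, region means, final energy, history."""

    mask: np.ndarray
    c_in: float
    c_out: float
    energy: float
    energy_history: list[float] = field(default_factory=list)
    n_iters: int = 0
    converged: bool = False


def _perimeter(mask: np.ndarray) -> int:
    """Count 4-adjacent pixel pairs with different labels (in-image only)."""
    return int(
        np.count_nonzero(mask[:, 1:] != mask[:, :-1])
        + np.count_nonzero(mask[1:, :] != mask[:-1, :])
    )


def _neighbor_counts(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(fg-neighbour count, total in-image neighbour count) per pixel."""
    m = mask.astype(np.int8)
    nfg = np.zeros(mask.shape, dtype=np.int8)
    nfg[:, 1:] += m[:, :-1]
    nfg[:, :-1] += m[:, 1:]
    nfg[1:, :] += m[:-1, :]
    nfg[:-1, :] += m[1:, :]
    ntot = np.full(mask.shape, 4, dtype=np.int8)
    ntot[0, :] -= 1
    ntot[-1, :] -= 1
    ntot[:, 0] -= 1
    ntot[:, -1] -= 1
    return nfg, ntot


def _means(g: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    n_in = int(np.count_nonzero(mask))
    if n_in == 0:
        c_out = float(g.mean())
        return c_out, c_out
    if n_in == g.size:
        c_in = float(g.mean())
        return c_in, c_in
    total = float(g.sum())
    s_in = float(g[mask].sum())
    return s_in / n_in, (total - s_in) / (g.size - n_in)


def chan_vese_energy(
    gray: np.ndarray, mask: np.ndarray, params: ChanVeseParams
) -> float:
    """Chan-Vese energy of a labelling, on intensities normalised to [0, 1]."""
    g = np.asarray(gray, dtype=np.float64) / 255.0
    mask = np.asarray(mask, dtype=bool)
    lam_in, lam_out = params.effective_lambdas()
    c_in, c_out = _means(g, mask)
    e_data = lam_in * float(((g[mask] - c_in) ** 2).sum()) + lam_out * float(
        ((g[~mask] - c_out) ** 2).sum()
    )
    return params.mu * _perimeter(mask) + e_data


def chan_vese(
    gray: np.ndarray,
    init_mask: np.ndarray,
    params: ChanVeseParams | None = None,
) -> tuple[np.ndarray, ContourState]:
    """Evolve ``init_mask`` to a (local) minimum of the Chan-Vese energy.

    Candidate pixels are the narrow band (8-neighbourhood of the current
    contour); two checkerboard half-sweeps per iteration flip every candidate
    whose exact energy change is negative.  Stops when the changed-pixel
    fraction falls below ``params.tol`` or after ``max_iters`` iterations.

    Raises on an empty initialisation; a constant image returns the
    initialisation unchanged with a warning (the two-region model is
    degenerate there).
    """
    params = params or ChanVeseParams()
    g = np.asarray(gray, dtype=np.float64) / 255.0
    mask = np.asarray(init_mask, dtype=bool).copy()
    if g.shape != mask.shape:
        raise ValueError("init_mask dimensions must match the image")
    if not mask.any():
        raise ValueError("empty initialization")
    if np.ptp(g) == 0:
        warnings.warn("constant image: Chan-Vese model is degenerate")
        c = float(g.mean()) * 255.0
        e = chan_vese_energy(gray, mask, params)
        return mask, ContourState(mask, c, c, e, [e], 0, True)

    lam_in, lam_out = params.effective_lambdas()
    mu = params.mu
    yy, xx = np.indices(g.shape)
    checker = (yy + xx) % 2 == 0
    struct8 = np.ones((3, 3), dtype=bool)

    energy_hist = [chan_vese_energy(gray, mask, params)]
    converged = False
    it = 0
    for it in range(1, params.max_iters + 1):
        c_in, c_out = _means(g, mask)
        d_in = lam_in * (g - c_in) ** 2     # cost of being inside
        d_out = lam_out * (g - c_out) ** 2  # cost of being outside
        changed = 0
        for color in (checker, ~checker):
            band = ndimage.binary_dilation(mask, struct8) & ~ndimage.binary_erosion(
                mask, struct8, border_value=1
            )
            nfg, ntot = _neighbor_counts(mask)
            # fg -> bg: dE = d_out - d_in + mu * (2*nfg - ntot)
            # bg -> fg: dE = d_in - d_out + mu * (ntot - 2*nfg)
            d_perim = mu * (2 * nfg.astype(np.float64) - ntot)
            de = np.where(mask, d_out - d_in + d_perim, d_in - d_out - d_perim)
            flips = band & color & (de < -1e-12)
            n = int(np.count_nonzero(flips))
            if n:
                mask[flips] = ~mask[flips]
                changed += n
            if not mask.any():
                # region vanished entirely: report empty, stop evolving
                break
        energy_hist.append(chan_vese_energy(gray, mask, params))
        if not mask.any():
            break
        if changed / mask.size < params.tol:
            converged = True
            break

    c_in, c_out = _means(g, mask) if mask.any() else (float("nan"), float(g.mean()))
    state = ContourState(
        mask=mask,
        c_in=c_in * 255.0,
        c_out=c_out * 255.0,
        energy=energy_hist[-1],
        energy_history=energy_hist,
        n_iters=it,
        converged=converged,
    )
    return mask, state


def _plant_box(
    mask: np.ndarray, margin_frac: float, shape: tuple[int, int]
) -> tuple[slice, slice]:
    ys, xs = np.nonzero(mask)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    my = max(int(round((y1 - y0) * margin_frac)), 8)
    mx = max(int(round((x1 - x0) * margin_frac)), 8)
    return (
        slice(max(y0 - my, 0), min(y1 + my, shape[0])),
        slice(max(x0 - mx, 0), min(x1 + mx, shape[1])),
    )


def propagate_dark_period(
    frames: list[Frame],
    seed_mask: LabeledMask,
    direction: str = "forward",
    params: ChanVeseParams | None = None,
    illumination: IlluminationParams | None = None,
    box_margin_frac: float = 0.25,
) -> list[LabeledMask]:
    """Chain Chan-Vese segmentations through a dark period, plant by plant.

    ``frames`` must already be ordered in the processing direction (reversed
    for a reverse pass).  Each plant evolves independently inside its bounding
    box dilated by ``box_margin_frac``; the converged mask seeds the next
    frame.  A plant whose mask vanishes is recorded empty for that frame, with
    a warning, and its last non-empty mask seeds the next frame.  When
    ``illumination`` is given, each NIR frame is corrected before evolution.
    """
    if direction not in ("forward", "reverse"):
        raise ValueError("direction must be 'forward' or 'reverse'")
    params = params or ChanVeseParams()
    bias = Direction.EXPAND if direction == "forward" else Direction.CONTRACT
    params = replace(params, direction=bias)

    current: dict[int, np.ndarray] = {
        pid: seed_mask.plant_mask(pid) for pid in seed_mask.plant_ids
    }
    out: list[LabeledMask] = []
    for frame in frames:
        gray = frame.luminance()
        if illumination is not None:
            gray = correct_illumination(gray, illumination)
        labels = np.zeros(gray.shape, dtype=np.int64)
        for pid in seed_mask.plant_ids:
            init = current[pid]
            if not init.any():
                continue
            ys, xs = _plant_box(init, box_margin_frac, gray.shape)
            sub, _ = chan_vese(gray[ys, xs], init[ys, xs], params)
            new = np.zeros_like(init)
            new[ys, xs] = sub
            if not new.any():
                warnings.warn(
                    f"plant {pid} mask vanished at frame {frame.frame_index}; "
                    "carrying last non-empty mask forward"
                )
                # record empty for this frame, keep previous init
            else:
                labels[new & (labels == 0)] = pid
                current[pid] = new
        out.append(LabeledMask(labels, seed_mask.plant_ids))
    return out


def average_passes(
    forward_areas: pd.DataFrame, reverse_areas: pd.DataFrame
) -> pd.DataFrame:
    """Per plant per frame, average the forward- and reverse-pass PRA.

    Both inputs are frame-indexed DataFrames with one column per plant; a
    missing (NaN) value in one pass falls back to the other pass alone.
    """
    if not forward_areas.index.equals(reverse_areas.index) or list(
        forward_areas.columns
    ) != list(reverse_areas.columns):
        raise ValueError("forward and reverse series cover different frames/plants")
    stacked = np.stack([forward_areas.to_numpy(float), reverse_areas.to_numpy(float)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pairs
        mean = np.nanmean(stacked, axis=0)
    return pd.DataFrame(mean, index=forward_areas.index, columns=forward_areas.columns)
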