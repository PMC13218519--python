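"""Frame registration and image post-processing for in vivo video stacks.

Scanning-ophthalmoscope videos are registered frame by frame against a
manually chosen template patch using zero-normalized cross-correlation
(NCC), low-correlation frames are dropped, and the surviving aligned
patches are averaged into a single image.  A percentile contrast stretch
replaces the manual adjustment step, and ``defocus_step_um`` converts a
region thickness and a number of focal steps into the axial step size.

Registration is integer-pixel only: the method is template matching over
the discrete offset grid, nothing finer.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from skimage.feature import match_template

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "RegistrationResult",
    "ncc_register",
    "contrast_stretch",
    "defocus_step_um",
    "synth_video",
]

DEFAULT_MIN_CORR = 0.5


@dataclass
class RegistrationResult:
    """Per-frame template locations, NCC peaks, keep flags and the average.

    ``offsets`` are the (row, col) positions of the best template match in
    each frame; ``shifts`` are offsets relative to a reference origin
    (the template's location in the source frame, when known).  The
    ``average`` image has the template's dimensions: it is the mean of
    the matched patches over kept frames.
    """

    offsets: np.ndarray  # (k, 2) int
    peaks: np.ndarray  # (k,) float in [-1, 1]
    kept: np.ndarray  # (k,) bool
    average: np.ndarray
    origin: tuple[int, int] = (0, 0)

    @property
    def shifts(self) -> np.ndarray:
        return self.offsets - np.asarray(self.origin)[None, :]

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())


def ncc_register(
    stack: np.ndarray,
    template: np.ndarray,
    min_corr: float = DEFAULT_MIN_CORR,
    origin: tuple[int, int] = (0, 0),
) -> RegistrationResult:
    """Register every frame to a template by zero-normalized
    cross-correlation over all valid integer offsets.

    Frames whose peak NCC falls below ``min_corr`` are dropped; the
    remaining matched patches are averaged.  The template must be
    strictly smaller than the frames and must not be constant.
    """
    stack = np.asarray(stack, dtype=float)
    template = np.asarray(template, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValidationError("stack must be (n_frames, H, W) with >= 1 frame")
    if not (0.0 <= min_corr <= 1.0):
        raise ValidationError("min_corr must be in [0, 1]")
    th, tw = template.shape
    _, fh, fw = stack.shape
    if th >= fh or tw >= fw:
        raise ValidationError("template must be strictly smaller than frames")
    if np.ptp(template) == 0:
        raise DegenerateInputError("template has zero variance")

    offsets = np.zeros((stack.shape[0], 2), dtype=int)
    peaks = np.zeros(stack.shape[0])
    for i, frame in enumerate(stack):
        corr = match_template(frame, template, pad_input=False)
        flat = int(np.argmax(corr))
        r, c = np.unravel_index(flat, corr.shape)
        offsets[i] = (r, c)
        peaks[i] = corr[r, c]

    kept = peaks >= min_corr
    if not kept.any():
        raise DegenerateInputError(
            f"all frames dropped: best peak NCC {peaks.max():.3f} "
            f"< min_corr {min_corr}"
        )
    patches = [
        stack[i, r : r + th, c : c + tw]
        for i, (r, c) in enumerate(offsets)
        if kept[i]
    ]
    average = np.mean(patches, axis=0)
    return RegistrationResult(
        offsets=offsets, peaks=peaks, kept=kept, average=average, origin=origin
    )


def contrast_stretch(
    image: np.ndarray, p_low: float = 1.0, p_high: float = 99.0
) -> np.ndarray:
    """Linear map sending the ``p_low``/``p_high`` percentiles to [0, 1],
    clipped; a flat image is returned unchanged with a warning."""
    if not (0.0 <= p_low < p_high <= 100.0):
        raise ValidationError("need 0 <= p_low < p_high <= 100")
    img = np.asarray(image, dtype=float)
    lo, hi = np.percentile(img, [p_low, p_high])
    if hi <= lo:
        warnings.warn("flat image: contrast stretch is a no-op")
        return img.copy()
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def defocus_step_um(region_thickness_um: float, n_steps: int) -> float:
    """Axial defocus step: region thickness divided by number of steps."""
    if not region_thickness_um > 0:
        raise ValidationError("region thickness must be > 0")
    if n_steps < 1:
        raise ValidationError("n_steps must be >= 1")
    return region_thickness_um / n_steps


def synth_video(
    template: np.ndarray,
    shifts: list[tuple[int, int]],
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    margin: int = 8,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Fixture generator: frames containing the template at known integer
    shifts plus seeded Gaussian noise.

    Returns ``(stack, base_offset)`` where ``base_offset`` is the
    template's (row, col) location at zero shift; the applied ``shifts``
    are the ground truth for registration tests.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    template = np.asarray(template, dtype=float)
    th, tw = template.shape
    fh, fw = th + 2 * margin, tw + 2 * margin
    base = (margin, margin)
    frames = np.zeros((len(shifts), fh, fw))
    for i, (dr, dc) in enumerate(shifts):
        r, c = base[0] + dr, base[1] + dc
        if not (0 <= r and r + th <= fh and 0 <= c and c + tw <= fw):
            raise ValidationError(f"shift {(dr, dc)} exceeds the frame margin")
        frames[i, r : r + th, c : c + tw] = template
        if noise_sd > 0:
            frames[i] += rng.normal(0.0, noise_sd, size=(fh, fw))
    return frames, base
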