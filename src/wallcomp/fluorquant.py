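"""Immunofluorescence quantification by fixed-size fragment sampling.

Labeling intensity is measured on the green channel only (after RGB
separation, values on a 0-254 scale).  Within a user-supplied binary
cell-wall mask, 4x4-pixel fragments are sampled — at least 30 for
thin-walled parenchyma and 50 for thick-walled collenchyma — and the
per-fragment mean intensities of two images are compared with a Student's
t-test at p < 0.05.  Fragments are placed uniformly at random without
overlap and entirely inside the mask (grid placement available); placement
is seeded and bit-reproducible.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np

from .composition_io import ValidationError
from .forward_sim import INTENSITY_MAX
from .group_stats import GroupComparison, compare_groups

FRAGMENT_SIZE = 4

#: Minimum fragments per image: thin-walled parenchyma 30, thick-walled
#: collenchyma 50.
N_MIN = {"Par": 30, "Col": 50}


@dataclass(frozen=True)
class FragmentSample:
    """Green-channel 4x4 fragments drawn from one masked wall image."""

    image_id: str
    tissue: str
    fragments: tuple  # of 4x4 ndarrays
    anchors: tuple  # (row, col) top-left corners
    n: int

    @property
    def fragment_means(self) -> np.ndarray:
        return np.array([f.mean() for f in self.fragments])


def green_channel(image: np.ndarray) -> np.ndarray:
    """Extract the G plane of an RGB image, clamped to [0, 254].

    Grayscale input is rejected — the caller must state which channel the
    signal lives in.  Values above 254 are clamped with a warning.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[-1] < 3:
        raise ValidationError(
            "expected an RGB image (H x W x 3); for single-channel input "
            "pass the intensity plane explicitly"
        )
    g = img[..., 1].astype(float)
    if g.max(initial=0) > INTENSITY_MAX:
        _warnings.warn(
            f"green values above {INTENSITY_MAX} clamped", stacklevel=2
        )
    return np.clip(g, 0, INTENSITY_MAX)


def _valid_anchors(mask: np.ndarray) -> np.ndarray:
    """Top-left corners whose 4x4 window lies entirely inside the mask."""
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 2:
        raise ValidationError("mask must be a 2-D binary array")
    k = FRAGMENT_SIZE
    if m.shape[0] < k or m.shape[1] < k:
        return np.empty((0, 2), dtype=int)
    # integral-image window sums: window fully masked iff sum == 16
    csum = np.pad(m.astype(int).cumsum(0).cumsum(1), ((1, 0), (1, 0)))
    win = (
        csum[k:, k:] - csum[:-k, k:] - csum[k:, :-k] + csum[:-k, :-k]
    )
    rows, cols = np.nonzero(win == k * k)
    return np.column_stack([rows, cols])


def sample_fragments(
    intensity: np.ndarray,
    mask: np.ndarray,
    tissue: str,
    seed: int = 0,
    *,
    n: int | None = None,
    image_id: str = "img",
    placement: str = "random",
) -> FragmentSample:
    """Draw non-overlapping, fully-masked 4x4 fragments from an image.

    ``n`` defaults to the tissue minimum (30 parenchyma / 50 collenchyma)
    and may only be raised above it.  ``placement='random'`` picks uniform
    random non-overlapping anchors (seeded); ``'grid'`` walks a
    deterministic 4-px grid.  Raises if the mask cannot host the requested
    count, reporting the achievable number.
    """
    if tissue not in N_MIN:
        raise ValidationError(f"tissue must be one of {sorted(N_MIN)}")
    n_min = N_MIN[tissue]
    if n is None:
        n = n_min
    elif n < n_min:
        raise ValidationError(
            f"n={n} below the {tissue} minimum of {n_min} fragments"
        )
    intensity = np.asarray(intensity, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if intensity.shape != mask.shape:
        raise ValidationError("intensity and mask shapes differ")

    anchors = _valid_anchors(mask)
    if len(anchors) == 0:
        raise ValidationError(
            "mask admits 0 fully-contained 4x4 fragments "
            f"(need {n}); wall region too thin or too small"
        )

    k = FRAGMENT_SIZE
    chosen: list[tuple[int, int]] = []
    occupied = np.zeros(mask.shape, dtype=bool)
    if placement == "grid":
        order = anchors[np.lexsort((anchors[:, 1], anchors[:, 0]))]
    elif placement == "random":
        rng = np.random.default_rng(seed)
        order = anchors[rng.permutation(len(anchors))]
    else:
        raise ValidationError("placement must be 'random' or 'grid'")

    for r, c in order:
        if occupied[r : r + k, c : c + k].any():
            continue
        occupied[r : r + k, c : c + k] = True
        chosen.append((int(r), int(c)))
        if len(chosen) == n:
            break
    if len(chosen) < n:
        raise ValidationError(
            f"mask hosts only {len(chosen)} non-overlapping 4x4 fragments; "
            f"{n} requested"
        )

    frags = tuple(
        intensity[r : r + k, c : c + k].copy() for r, c in chosen
    )
    return FragmentSample(
        image_id=image_id,
        tissue=tissue,
        fragments=frags,
        anchors=tuple(chosen),
        n=len(chosen),
    )


def compare_images(a: FragmentSample, b: FragmentSample) -> GroupComparison:
    """Student's t-test on the per-fragment mean intensities of two samples.

    Significant at p < 0.05 (tier '*'); the looser '**' tier is carried
    through from the shared comparison machinery but plays no role here.
    """
    return compare_groups(
        "green_intensity",
        (a.tissue, 0),
        (b.tissue, 0),
        a.fragment_means,
        b.fragment_means,
    )


__all__ = [
    "FRAGMENT_SIZE",
    "N_MIN",
    "FragmentSample",
    "green_channel",
    "sample_fragments",
    "compare_images",
]
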