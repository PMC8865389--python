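"""Diagnostically constrained soft labels from singular-value signatures.

Only one or two tissue slices on a slide carry the region of interest (ROI)
that supports the diagnosis; the remaining slices frequently belong to a
*lower* diagnostic category than the slide as a whole. Instead of copying the
slide label onto every slice (the multiple-instance-learning default), slices
without an ROI receive a probability vector over categories:

1. every slice is summarized by the descending vector of its top-``d``
   singular values, computed on a canonically resized grayscale crop;
2. ROI-bearing slices of each category are averaged into a per-category
   prototype profile;
3. a non-ROI slice's soft label is the softmax of its profile's similarity
   to each prototype;
4. the diagnostic constraint zeroes all categories at or above the slide's
   category ``k`` and renormalizes the remainder.

Profiles and prototypes are l2-normalized before the similarity dot product,
so the logits are cosine similarities; raw singular values scale with image
size and would saturate the softmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import svdvals
from skimage.transform import resize
from skimage.util import img_as_float

from .slide_prep import CLASS_NAMES, TissueSlice

#: Length of the singular-value signature.
DEFAULT_D = 50
#: Canonical (height, width) every crop is resized to before the SVD, so
#: profiles from differently sized slices are comparable.
CANONICAL_SIZE = (512, 512)

LABEL_KINDS = ("hard", "smoothed", "constrained_smoothed", "soft", "constrained_soft")


@dataclass(frozen=True)
class SingularProfile:
    """Descending vector of the top-``d`` singular values of one slice."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1:
            raise ValueError("profile must be a vector")
        if np.any(v < 0) or np.any(np.diff(v) > 1e-9):
            raise ValueError("singular values must be non-negative and descending")

    @property
    def d(self) -> int:
        return self.values.shape[0]

    def unit(self) -> np.ndarray:
        norm = np.linalg.norm(self.values)
        if norm == 0:
            raise ValueError("cannot normalize an all-zero profile")
        return self.values / norm


@dataclass(frozen=True)
class ClassPrototypes:
    """Per-category mean singular profiles, fitted on ROI-bearing slices."""

    s_bar: np.ndarray  # (C, d)

    @property
    def n_classes(self) -> int:
        return self.s_bar.shape[0]

    @property
    def d(self) -> int:
        return self.s_bar.shape[1]


@dataclass(frozen=True)
class LabelVector:
    """Point on the C-simplex with the labeling scheme that produced it."""

    probs: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if self.kind not in LABEL_KINDS:
            raise ValueError(f"unknown label kind {self.kind!r}")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("label probabilities must be non-negative and sum to 1")

    @property
    def n_classes(self) -> int:
        return self.probs.shape[0]

    def argmax_class(self) -> int:
        """1-based index of the most probable category."""
        return int(np.argmax(self.probs)) + 1


def slice_singular_profile(
    crop: np.ndarray,
    d: int = DEFAULT_D,
    canonical_size: tuple[int, int] = CANONICAL_SIZE,
) -> SingularProfile:
    """Singular-value signature of one tissue-slice crop.

    The crop is converted to grayscale in [0, 1], resized to
    ``canonical_size`` and decomposed; the descending singular values are
    truncated (or zero-padded) to length ``d``.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    if crop.size == 0:
        raise ValueError("empty crop")
    img = img_as_float(crop)
    if img.ndim == 3:
        img = img[..., :3] @ np.array([0.2125, 0.7154, 0.0721])
    if img.shape != canonical_size:
        img = resize(img, canonical_size, order=1, anti_aliasing=True, preserve_range=True)
    s = svdvals(img)
    out = np.zeros(d)
    k = min(d, s.shape[0])
    out[:k] = s[:k]
    return SingularProfile(out)


def fit_class_prototypes(
    roi_profiles: list[tuple[SingularProfile, int]],
    n_classes: int = len(CLASS_NAMES),
) -> ClassPrototypes:
    """Mean singular profile per category, from ROI-bearing slices only.

    ``roi_profiles`` pairs each profile with its 1-based category index.
    Every category must contribute at least one slice.
    """
    if not roi_profiles:
        raise ValueError("no ROI profiles given")
    d = roi_profiles[0][0].d
    sums = np.zeros((n_classes, d))
    counts = np.zeros(n_classes, dtype=int)
    for profile, class_index in roi_profiles:
        if not 1 <= class_index <= n_classes:
            raise ValueError(f"class index {class_index} outside 1..{n_classes}")
        sums[class_index - 1] += profile.values
        counts[class_index - 1] += 1
    missing = [CLASS_NAMES[i] for i in range(n_classes) if counts[i] == 0]
    if missing:
        raise ValueError(f"no ROI-bearing slices for class(es): {', '.join(missing)}")
    return ClassPrototypes(sums / counts[:, None])


def soft_label(
    profile: SingularProfile,
    prototypes: ClassPrototypes,
    normalize: bool = True,
) -> LabelVector:
    """Softmax over per-category profile similarities (kind ``soft``)."""
    if profile.d != prototypes.d:
        raise ValueError("profile and prototypes have different d")
    if normalize:
        protos = prototypes.s_bar / np.linalg.norm(prototypes.s_bar, axis=1, keepdims=True)
        logits = protos @ profile.unit()
    else:
        logits = prototypes.s_bar @ profile.values
    if not np.all(np.isfinite(logits)):
        raise ValueError("non-finite similarity; profiles appear unnormalized")
    e = np.exp(logits - logits.max())
    return LabelVector(e / e.sum(), kind="soft")


def constrain_label(y_hat: LabelVector, k: int) -> LabelVector:
    """Apply the diagnostic constraint for a slide of category ``k``.

    Non-ROI slices may only belong to categories strictly below the slide's:
    entries for categories >= k become exactly 0 and the entries below k are
    renormalized to sum to 1.
    """
    c = y_hat.n_classes
    if k == 1:
        raise ValueError(
            "k=1 has no lower category; assign the hard class-1 label instead"
        )
    if not 1 < k <= c:
        raise ValueError(f"k={k} outside 2..{c}")
    allowed = y_hat.probs[: k - 1]
    total = allowed.sum()
    if total <= 0:
        raise ValueError("no probability mass below category k; cannot renormalize")
    probs = np.zeros(c)
    probs[: k - 1] = allowed / total
    return LabelVector(probs, kind="constrained_soft")


def baseline_labels(
    class_index: int,
    scheme: str,
    epsilon: float = 0.1,
    n_classes: int = len(CLASS_NAMES),
    has_roi: bool = False,
) -> LabelVector:
    """Reference labeling schemes the soft labels are compared against.

    ``hard``: one-hot at the slide category. ``smoothed``: 1 - epsilon on the
    slide category, epsilon/(C-1) on each other. ``constrained_smoothed``:
    ROI slices keep the one-hot label; non-ROI slices get a uniform
    distribution over the categories strictly below the slide's (one-hot at
    category 1 when the slide is category 1, where no lower category exists).
    """
    if not 1 <= class_index <= n_classes:
        raise ValueError(f"class index {class_index} outside 1..{n_classes}")
    if not 0 <= epsilon < 1:
        raise ValueError("epsilon must be in [0, 1)")
    k = class_index - 1
    if scheme == "hard":
        probs = np.zeros(n_classes)
        probs[k] = 1.0
        return LabelVector(probs, kind="hard")
    if scheme == "smoothed":
        probs = np.full(n_classes, epsilon / (n_classes - 1))
        probs[k] = 1.0 - epsilon
        return LabelVector(probs, kind="smoothed")
    if scheme == "constrained_smoothed":
        probs = np.zeros(n_classes)
        if has_roi or class_index == 1:
            probs[k] = 1.0
        else:
            probs[:k] = 1.0 / k
        return LabelVector(probs, kind="constrained_smoothed")
    raise ValueError(f"unknown scheme {scheme!r}")


def assign_slice_labels(
    slices_by_slide: dict[str, list[TissueSlice]],
    slide_classes: dict[str, int],
    scheme: str = "constrained_soft",
    d: int = DEFAULT_D,
    epsilon: float = 0.1,
    n_classes: int = len(CLASS_NAMES),
    profile_scale: str = "10x",
    prototypes: ClassPrototypes | None = None,
) -> ClassPrototypes | None:
    """Attach a :class:`LabelVector` to every slice, in place.

    For the ``constrained_soft`` scheme, prototypes are fitted on the
    ROI-bearing slices of the given slides unless supplied. ROI-bearing
    slices always keep the hard slide label; category-1 slides label every
    slice hard (no lower category exists). Returns the prototypes used, if
    any.
    """
    if scheme in ("hard", "smoothed", "constrained_smoothed"):
        for slide_id, slices in slices_by_slide.items():
            k = slide_classes[slide_id]
            for sl in slices:
                if scheme == "constrained_smoothed" and sl.has_roi:
                    sl.label = baseline_labels(k, "hard", n_classes=n_classes)
                else:
                    sl.label = baseline_labels(
                        k, scheme, epsilon=epsilon, n_classes=n_classes, has_roi=sl.has_roi
                    )
        return None
    if scheme != "constrained_soft":
        raise ValueError(f"unknown scheme {scheme!r}")

    profiles: dict[tuple[str, str], SingularProfile] = {}
    for slide_id, slices in slices_by_slide.items():
        for sl in slices:
            profiles[(slide_id, sl.slice_id)] = slice_singular_profile(
                sl.crops[profile_scale], d=d
            )
    if prototypes is None:
        roi = [
            (profiles[(slide_id, sl.slice_id)], slide_classes[slide_id])
            for slide_id, slices in slices_by_slide.items()
            for sl in slices
            if sl.has_roi
        ]
        prototypes = fit_class_prototypes(roi, n_classes=n_classes)
    for slide_id, slices in slices_by_slide.items():
        k = slide_classes[slide_id]
        for sl in slices:
            if sl.has_roi or k == 1:
                sl.label = baseline_labels(k, "hard", n_classes=n_classes)
            else:
                y_hat = soft_label(profiles[(slide_id, sl.slice_id)], prototypes)
                sl.label = constrain_label(y_hat, k)
    return prototypes
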