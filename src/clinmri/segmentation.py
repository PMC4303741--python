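"""Atlas-trained kNN brain-tissue segmentation and volumetry.

The segmentation follows the multi-atlas / subject-trained scheme: each
atlas is registered (affine, then coarse non-rigid, both maximising mutual
information) to the bias-corrected subject image; the transformed expert
labels are averaged into a tissue probability map; voxels where all atlases
agree supply training intensities for a k-nearest-neighbour classifier that
is therefore trained on the subject's own contrast; the classifier labels
every voxel inside the intracranial mask as CSF, grey or white matter.
Because training samples come from the target image itself, atlas/subject
contrast differences are absorbed by the registration and never bias the
intensity model.

Volumes are voxel counts times voxel volume: brain = GM + WM and
ICV = CSF + GM + WM hold exactly by construction.

The kNN decision is defined over the *inclusive shell*: every training
sample whose distance does not exceed the k-th smallest distance votes.
With quantised intensities many samples are equidistant, and the inclusive
shell is the unique order-independent completion of "the k nearest"; class
ties are broken by smaller mean neighbour distance, then CSF < GM < WM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .dicom_io import (
    BACKGROUND,
    CSF,
    GM,
    TISSUE_CLASSES,
    WM,
    HeaderRecord,
    ImageVolume,
    LabelVolume,
)
from .phantom import AtlasSet
from .registration import (
    RegistrationConfig,
    RegistrationError,
    affine_register,
    apply_transform,
    nonrigid_register,
)

__all__ = [
    "BiasConfig",
    "ProbabilityMap",
    "KnnConfig",
    "KnnModel",
    "BiomarkerRecord",
    "correct_bias",
    "build_probability_map",
    "majority_mask",
    "sample_training_set",
    "knn_segment",
    "compute_volumes",
    "segment_examination",
]


# ---------------------------------------------------------------------------
# Bias-field correction


@dataclass(frozen=True)
class BiasConfig:
    """Low-order smooth-field correction parameters.

    ``order``-degree polynomial field fitted in log-intensity space over the
    foreground, alternating with a ``n_clusters``-way intensity clustering
    so tissue structure is not absorbed into the field.
    """

    order: int = 2
    iterations: int = 3
    n_clusters: int = 5
    foreground_quantile: float = 0.5  # of Otsu threshold


def _polynomial_terms(volume: ImageVolume, order: int) -> np.ndarray:
    """Monomial design (n_voxels, n_terms) over [-1, 1]-normalised coords."""
    x, y, z = volume.index_coords()
    center = [(lo + hi) / 2 for lo, hi in ((c.min(), c.max()) for c in (x, y, z))]
    half = [max((c.max() - c.min()) / 2, 1e-9) for c in (x, y, z)]
    xn = (x - center[0]) / half[0]
    yn = (y - center[1]) / half[1]
    zn = (z - center[2]) / half[2]
    terms = [np.ones_like(xn)]
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                if i + j + k == 0:
                    continue
                terms.append(xn**i * yn**j * zn**k)
    return np.stack([t.ravel() for t in terms], axis=1)


def _cluster_means(values: np.ndarray, k: int, iterations: int = 10) -> np.ndarray:
    """Tiny deterministic 1-D k-means (quantile-initialised Lloyd)."""
    centers = np.quantile(values, np.linspace(0.05, 0.95, k))
    for _ in range(iterations):
        assign = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
        for c in range(k):
            sel = assign == c
            if sel.any():
                centers[c] = values[sel].mean()
        centers.sort()
    assign = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
    return centers[assign]


def correct_bias(
    image: ImageVolume, config: BiasConfig | None = None
) -> tuple[ImageVolume, np.ndarray]:
    """Estimate and divide out a smooth multiplicative intensity field.

    Works in log space: foreground voxels are clustered by intensity, the
    residual (log intensity minus assigned cluster mean) is fitted with a
    low-order polynomial, and the exponentiated fit is the field.  The
    field is strictly positive, normalised to unit geometric mean over the
    foreground, and the corrected image is rescaled so the foreground mean
    intensity is preserved.
    """
    from skimage.filters import threshold_otsu

    config = config or BiasConfig()
    data = np.asarray(image.data, dtype=np.float64)
    if not np.any(data > 0):
        raise ValueError("cannot bias-correct an all-zero image")
    fg = data > config.foreground_quantile * threshold_otsu(data[data > 0])
    if fg.sum() < 100:
        raise ValueError("too little foreground to estimate a bias field")

    design = _polynomial_terms(image, config.order)
    log_data = np.log(np.where(data > 0, data, 1.0))
    log_field = np.zeros(data.size)
    fg_flat = fg.ravel()
    for _ in range(config.iterations):
        corrected = log_data.ravel() - log_field
        assigned = _cluster_means(corrected[fg_flat], config.n_clusters)
        residual = corrected[fg_flat] - assigned
        coeffs, *_ = np.linalg.lstsq(design[fg_flat], log_field[fg_flat] + residual,
                                     rcond=None)
        log_field = design @ coeffs
    log_field -= log_field[fg_flat].mean()  # unit geometric mean on foreground
    fld = np.exp(log_field).reshape(data.shape)

    corrected = data / fld
    scale = data[fg].mean() / corrected[fg].mean()
    return image.with_data(corrected * scale), fld


# ---------------------------------------------------------------------------
# Probability map and masks


@dataclass
class ProbabilityMap:
    """Per-class vote fractions on the subject grid.

    ``probabilities`` has shape (4, *grid) ordered (background, CSF, GM,
    WM); each voxel's probabilities sum to 1 and, with n atlases, every
    probability is a multiple of 1/n.
    """

    probabilities: np.ndarray
    n_atlases: int
    geometry: ImageVolume

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities)
        if p.shape[0] != 4:
            raise ValueError("expected 4 class planes (background, CSF, GM, WM)")
        if np.any(p < -1e-9):
            raise ValueError("negative probabilities")
        if np.max(np.abs(p.sum(axis=0) - 1.0)) > 1e-6:
            raise ValueError("probabilities must sum to 1 at every voxel")

    def class_probability(self, cls: int) -> np.ndarray:
        return self.probabilities[cls]


def build_probability_map(
    atlases: AtlasSet,
    subject: ImageVolume,
    config: RegistrationConfig | None = None,
) -> tuple[ProbabilityMap, dict[str, list[np.ndarray]]]:
    """Register every atlas to the subject and average the labels.

    Each atlas goes through affine then coarse non-rigid registration by
    mutual information; its label image and masks are carried over
    nearest-neighbour.  A failing atlas is dropped with a warning; if all
    fail the error propagates.  Returns the probability map and the
    per-atlas transformed ``intracranial`` and ``cerebrum`` masks.
    """
    config = config or RegistrationConfig()
    if atlases.count < 1:
        raise ValueError("need at least one atlas")
    votes = np.zeros((4,) + subject.shape)
    masks: dict[str, list[np.ndarray]] = {"intracranial": [], "cerebrum": []}
    used = 0
    for i, atlas in enumerate(atlases):
        try:
            affine, _ = affine_register(atlas.intensity, subject, config)
            fld, _ = nonrigid_register(atlas.intensity, subject, affine, config)
        except RegistrationError as exc:
            warnings.warn(f"atlas {i} dropped: {exc}")
            continue
        warped_labels = apply_transform(atlas.labels, fld, subject, "nearest")
        for cls in (BACKGROUND, CSF, GM, WM):
            votes[cls] += warped_labels.data == cls
        for name, mask in (
            ("intracranial", atlas.intracranial_mask),
            ("cerebrum", atlas.cerebrum_mask),
        ):
            mask_vol = ImageVolume(
                mask.astype(np.float64),
                atlas.intensity.spacing,
                atlas.intensity.origin,
                atlas.intensity.direction,
            )
            warped = apply_transform(mask_vol, fld, subject, "nearest")
            masks[name].append((warped.data > 0.5).astype(np.uint8))
        used += 1
    if used == 0:
        raise RegistrationError("all atlas registrations failed")
    pmap = ProbabilityMap(votes / used, used, subject)
    return pmap, masks


def majority_mask(masks: list[np.ndarray], threshold: float = 0.8) -> np.ndarray:
    """Combine binary masks by majority voting.

    A voxel is included iff the fraction of masks voting for it is at least
    ``threshold`` (0.8 by default: 5 of 6 atlases suffice, 4 do not).
    """
    if not masks:
        raise ValueError("no masks to vote over")
    stack = np.stack([np.asarray(m) > 0 for m in masks])
    return (stack.mean(axis=0) >= threshold).astype(np.uint8)


# ---------------------------------------------------------------------------
# kNN classifier


@dataclass(frozen=True)
class KnnConfig:
    k: int = 45
    max_per_class: int = 2000
    prob_threshold: float = 1.0  # unanimous atlas agreement
    seed: int = 0


@dataclass
class KnnModel:
    """Training samples and decision parameters of the voxel classifier."""

    features: np.ndarray  # (n_samples, n_features)
    classes: np.ndarray  # (n_samples,) values in {CSF, GM, WM}
    k: int
    tie_rule: str = (
        "inclusive shell at the k-th distance; class ties by smaller mean "
        "neighbour distance, then CSF < GM < WM"
    )

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=np.float64))
        self.classes = np.asarray(self.classes)
        if not np.all(np.isfinite(self.features)):
            raise ValueError("non-finite training features")
        if self.k < 1:
            raise ValueError("k must be positive")
        for cls in TISSUE_CLASSES:
            if (self.classes == cls).sum() < self.k:
                raise ValueError(
                    f"class {cls} has fewer than k={self.k} training samples"
                )


def _stack_features(image: ImageVolume | list[ImageVolume]) -> np.ndarray:
    """Per-voxel feature matrix; multi-channel input stacks intensities."""
    channels = image if isinstance(image, (list, tuple)) else [image]
    shape = channels[0].shape
    for ch in channels:
        if ch.shape != shape:
            raise ValueError("feature channels must share a grid")
    return np.stack([np.asarray(ch.data, dtype=np.float64).ravel()
                     for ch in channels], axis=1)


def sample_training_set(
    image: ImageVolume | list[ImageVolume],
    pmap: ProbabilityMap,
    config: KnnConfig | None = None,
) -> KnnModel:
    """Extract high-confidence training samples from the subject image.

    Candidates per tissue class are voxels whose class probability reaches
    ``prob_threshold`` (default 1.0: unanimous atlas agreement), subsampled
    uniformly (seeded) to ``max_per_class``.  If a class has fewer than k
    candidates the threshold is lowered stepwise by 1/n_atlases with a
    warning; a class that stays short is an error.
    """
    config = config or KnnConfig()
    features = _stack_features(image)
    rng = np.random.default_rng(config.seed)
    sampled_feats, sampled_classes = [], []
    for cls in TISSUE_CLASSES:
        prob = pmap.class_probability(cls).ravel()
        step = 1.0 / pmap.n_atlases
        threshold = config.prob_threshold
        idx = np.flatnonzero(prob >= threshold - 1e-9)
        # fallback floor is one atlas vote: below that "likely" loses meaning
        while idx.size < config.k and threshold - step > step - 1e-9:
            threshold = max(threshold - step, step)
            warnings.warn(
                f"class {cls}: lowering sampling threshold to {threshold:.3f}"
            )
            idx = np.flatnonzero(prob >= threshold - 1e-9)
        if idx.size < config.k:
            raise ValueError(
                f"class {cls} has only {idx.size} candidate voxels; "
                "cannot train the classifier"
            )
        if idx.size > config.max_per_class:
            idx = rng.choice(idx, size=config.max_per_class, replace=False)
            idx.sort()
        sampled_feats.append(features[idx])
        sampled_classes.append(np.full(idx.size, cls))
    return KnnModel(
        np.concatenate(sampled_feats),
        np.concatenate(sampled_classes),
        config.k,
    )


def _decide(counts: np.ndarray, mean_dists: np.ndarray) -> np.ndarray:
    """Pick the winning tissue per query row.

    ``counts``/``mean_dists`` are (n, 3) over (CSF, GM, WM); more votes
    wins, ties go to the smaller mean neighbour distance, then to the
    lower class code.
    """
    best_cls = np.full(counts.shape[0], TISSUE_CLASSES[0], dtype=np.int16)
    best_count = counts[:, 0].copy()
    best_mean = mean_dists[:, 0].copy()
    for col, cls in enumerate(TISSUE_CLASSES[1:], start=1):
        better = (counts[:, col] > best_count) | (
            (counts[:, col] == best_count) & (mean_dists[:, col] < best_mean)
        )
        best_cls[better] = cls
        best_count[better] = counts[better, col]
        best_mean[better] = mean_dists[better, col]
    return best_cls


def _shell_vote(dists: np.ndarray, labels: np.ndarray, kth: np.ndarray) -> np.ndarray:
    """Vote over the inclusive shell within a padded neighbour matrix."""
    in_shell = dists <= kth[:, None]
    counts = np.empty((dists.shape[0], len(TISSUE_CLASSES)))
    means = np.empty_like(counts)
    for col, cls in enumerate(TISSUE_CLASSES):
        sel = in_shell & (labels == cls)
        n = sel.sum(axis=1)
        counts[:, col] = n
        means[:, col] = np.where(
            n > 0,
            np.where(sel, dists, 0.0).sum(axis=1) / np.maximum(n, 1),
            np.inf,
        )
    return _decide(counts, means)


def knn_segment(
    image: ImageVolume | list[ImageVolume],
    model: KnnModel,
    icv_mask: np.ndarray,
) -> LabelVolume:
    """Label every intracranial voxel as CSF, GM or WM.

    Voxels outside ``icv_mask`` are background; inside, the inclusive-shell
    kNN vote decides (see module docstring).  Background is not a class
    inside the mask: all intracranial voxels are forced into a tissue.
    """
    primary = image[0] if isinstance(image, (list, tuple)) else image
    mask = np.asarray(icv_mask) > 0
    if mask.shape != primary.shape:
        raise ValueError("ICV mask must live on the image grid")
    features = _stack_features(image)
    labels = np.full(primary.shape, BACKGROUND, dtype=np.int16)
    inside = np.flatnonzero(mask.ravel())
    if inside.size:
        n_train = model.features.shape[0]
        pad = min(model.k + 32, n_train)
        nn = NearestNeighbors(n_neighbors=pad).fit(model.features)
        query = features[inside]
        dists, idx = nn.kneighbors(query)
        kth = dists[:, model.k - 1]
        nlab = model.classes[idx]
        labels_flat = _shell_vote(dists, nlab, kth)
        # queries whose shell extends past the padded neighbour list need
        # the exact shell from a radius query (grouped by shared radius)
        incomplete = np.flatnonzero(~((dists[:, -1] > kth) | (pad == n_train)))
        if incomplete.size:
            order = incomplete[np.argsort(kth[incomplete], kind="stable")]
            pos = 0
            while pos < order.size:
                r = kth[order[pos]]
                end = pos
                while end < order.size and kth[order[end]] == r:
                    end += 1
                sel = order[pos:end]
                d_list, i_list = nn.radius_neighbors(
                    query[sel], radius=r, sort_results=False
                )
                width = max(len(d) for d in d_list)
                d_mat = np.full((len(sel), width), np.inf)
                l_mat = np.full((len(sel), width), -1, dtype=np.int16)
                for row, (d, i) in enumerate(zip(d_list, i_list)):
                    d_mat[row, : len(d)] = d
                    l_mat[row, : len(d)] = model.classes[i]
                labels_flat[sel] = _shell_vote(d_mat, l_mat, np.full(len(sel), r))
                pos = end
        labels.ravel()[inside] = labels_flat
    return LabelVolume(labels, primary.spacing, primary.origin,
                       primary.direction.copy())


# ---------------------------------------------------------------------------
# Volumetry


@dataclass
class BiomarkerRecord:
    """Volumetric biomarkers and covariates of one examination (ml)."""

    pseudo_id: str
    age: int | None = None
    gender: str = ""
    group: str = ""
    scanner_model: str = ""
    field_strength: float = 0.0
    sequence: str = ""
    csf_ml: float = 0.0
    gm_ml: float = 0.0
    wm_ml: float = 0.0
    brain_ml: float = 0.0
    icv_ml: float = 0.0
    cerebrum_brain_ml: float = 0.0

    def __post_init__(self) -> None:
        for name in ("csf_ml", "gm_ml", "wm_ml"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def compute_volumes(
    labels: LabelVolume,
    cerebrum_mask: np.ndarray | None = None,
    header: HeaderRecord | None = None,
    pseudo_id: str = "",
) -> BiomarkerRecord:
    """Tissue volumes in ml from label counts times voxel volume.

    ``brain = GM + WM`` and ``ICV = CSF + GM + WM`` are computed as those
    exact sums.  When a cerebrum mask (majority-voted, cerebellum excluded)
    is given, the cerebrum-restricted brain volume is reported alongside.
    """
    vv_ml = labels.voxel_volume / 1000.0
    csf = float((labels.data == CSF).sum()) * vv_ml
    gm = float((labels.data == GM).sum()) * vv_ml
    wm = float((labels.data == WM).sum()) * vv_ml
    cerebrum = 0.0
    if cerebrum_mask is not None:
        if cerebrum_mask.shape != labels.shape:
            raise ValueError("cerebrum mask must live on the label grid")
        inside = np.asarray(cerebrum_mask) > 0
        cerebrum = float(
            np.isin(labels.data, [GM, WM])[inside].sum()
        ) * vv_ml
    record = BiomarkerRecord(
        pseudo_id=pseudo_id,
        csf_ml=csf,
        gm_ml=gm,
        wm_ml=wm,
        brain_ml=gm + wm,
        icv_ml=csf + gm + wm,
        cerebrum_brain_ml=cerebrum,
    )
    if header is not None:
        record.scanner_model = header.model
        record.field_strength = header.field_strength
    return record


def segment_examination(
    image: ImageVolume | list[ImageVolume],
    atlases: AtlasSet,
    registration_config: RegistrationConfig | None = None,
    knn_config: KnnConfig | None = None,
    bias_config: BiasConfig | None = None,
    mask_threshold: float = 0.8,
    pseudo_id: str = "",
) -> tuple[LabelVolume, BiomarkerRecord]:
    """Full biomarker extraction for one examination.

    Bias-correct, build the multi-atlas probability map, vote the
    intracranial and cerebrum masks (threshold ``mask_threshold``), train
    the subject kNN classifier on unanimous voxels and segment.
    """
    channels = image if isinstance(image, (list, tuple)) else [image]
    corrected = [correct_bias(ch, bias_config)[0] for ch in channels]
    primary = corrected[0]
    pmap, masks = build_probability_map(atlases, primary, registration_config)
    icv_mask = majority_mask(masks["intracranial"], mask_threshold)
    cerebrum = majority_mask(masks["cerebrum"], mask_threshold)
    model = sample_training_set(corrected, pmap, knn_config)
    labels = knn_segment(corrected, model, icv_mask)
    record = compute_volumes(labels, cerebrum, pseudo_id=pseudo_id)
    return labels, record
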