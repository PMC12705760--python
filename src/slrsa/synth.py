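"""Synthetic study inputs: designs, semantic spaces, listings, and BOLD data.

This module generates every input the real study acquired, at desk scale:
a jittered rapid event-related lexical-decision design (64 word + 64
pseudoword trials of 2400 ms), the three block-design localizer protocols,
a latent-factor semantic vector space standing in for the word2vec
embedding, property-listing tables over the 11 modal feature categories
with occasional missing cells, and 4-D BOLD volumes in which a known
representational geometry is planted so that every downstream stage
(trial-wise GLM, searchlight RSA, group inference) can be verified against
ground truth.

Pattern planting is exact: the target RDM is converted to a correlation
matrix, factorized, and mixed with centered orthonormal voxel bases, so the
planted patterns' sample correlation matrix equals the target exactly and a
zero-noise run of the full pipeline is an identity test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import stats

from . import glm
from .rdm import RDM

__all__ = [
    "CATEGORIES",
    "VOWELS",
    "SemanticMatrix",
    "PropertyListings",
    "EventDesign",
    "VolumeSeries",
    "PatternSet",
    "make_semantic_space",
    "make_property_listings",
    "make_event_design",
    "make_block_design",
    "assign_stimuli",
    "embed_geometry",
    "simulate_bold",
    "ar1_noise",
    "draw_itis",
    "generate_pseudoword",
    "sequence_ok",
    "length_match_test",
    "ellipsoid_mask",
    "ball_roi",
]

#: the 11 modal feature categories used to code listed properties
CATEGORIES = (
    "visual",
    "motor-related",
    "acoustic",
    "tactile",
    "olfactory",
    "gustatory",
    "interoceptive",
    "social constellation",
    "mental state",
    "emotion",
    "verbal association",
)

#: German vowel inventory (stimuli are German words)
VOWELS = frozenset("aeiouäöü")
_CONSONANTS = "bcdfghjklmnpqrstvwxyz"

#: scanner repetition time of the emulated acquisition, seconds
DEFAULT_TR = 2.0


# ---------------------------------------------------------------------------
# containers

@dataclass(frozen=True)
class SemanticMatrix:
    """Concepts x dimensions matrix of (unitless) embedding coordinates."""

    concepts: tuple
    vectors: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "concepts", tuple(self.concepts))
        v = np.asarray(self.vectors, dtype=float)
        if v.ndim != 2 or v.shape[0] != len(self.concepts):
            raise ValueError("one vector row per concept label required")
        if np.any(~v.any(axis=1)):
            raise ValueError("all-zero vectors have undefined correlation")
        object.__setattr__(self, "vectors", v)

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset(
                "labels",
                data=np.array([str(c) for c in self.concepts], dtype=object),
                dtype=h5py.string_dtype("utf-8"),
            )
            f.create_dataset("vectors", data=self.vectors)

    @classmethod
    def load_hdf5(cls, path) -> "SemanticMatrix":
        import h5py

        with h5py.File(path, "r") as f:
            if "labels" not in f or "vectors" not in f:
                raise ValueError(f"{path}: need 'labels' and 'vectors' datasets")
            labels = [
                x.decode("utf-8") if isinstance(x, bytes) else str(x)
                for x in f["labels"][()]
            ]
            vectors = np.asarray(f["vectors"][()], dtype=float)
        return cls(concepts=labels, vectors=vectors)

    @classmethod
    def load_text(cls, path) -> "SemanticMatrix":
        """Whitespace-delimited text with a leading label column."""
        df = pd.read_csv(path, sep=r"\s+", header=None, index_col=0)
        return cls(concepts=[str(i) for i in df.index],
                   vectors=df.to_numpy(dtype=float))


@dataclass(frozen=True)
class PropertyListings:
    """Participant x concept x category property counts with missing flags.

    ``missing`` holds (participant, concept) label pairs for which no
    listing exists; counts at those cells are flagged, never silently zero.
    """

    participants: tuple
    concepts: tuple
    counts: np.ndarray = field(repr=False)
    missing: frozenset = frozenset()
    categories: tuple = CATEGORIES

    def __post_init__(self):
        object.__setattr__(self, "participants", tuple(self.participants))
        object.__setattr__(self, "concepts", tuple(self.concepts))
        object.__setattr__(self, "categories", tuple(self.categories))
        object.__setattr__(self, "missing", frozenset(self.missing))
        if len(self.categories) != 11:
            raise ValueError("the category axis must have exactly 11 entries")
        c = np.asarray(self.counts)
        expected = (len(self.participants), len(self.concepts), 11)
        if c.shape != expected:
            raise ValueError(f"counts shape {c.shape} != {expected}")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", c.astype(int))

    def to_frame(self) -> pd.DataFrame:
        """Long format (participant, concept, category, count); missing
        cells are omitted entirely."""
        rows = []
        for pi, p in enumerate(self.participants):
            for ci, c in enumerate(self.concepts):
                if (p, c) in self.missing:
                    continue
                for ki, k in enumerate(self.categories):
                    rows.append((p, c, k, int(self.counts[pi, ci, ki])))
        return pd.DataFrame(
            rows, columns=["participant", "concept", "category", "count"]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PropertyListings":
        df = pd.read_csv(path, sep="\t")
        need = {"participant", "concept", "category", "count"}
        if not need.issubset(df.columns):
            raise ValueError(f"{path}: columns {sorted(need)} required")
        # lexicographic order: stable regardless of which cells are missing
        participants = sorted(set(df["participant"]))
        concepts = sorted(set(df["concept"]))
        cat_idx = {c: i for i, c in enumerate(CATEGORIES)}
        unknown = set(df["category"]) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"{path}: unknown categories {sorted(unknown)}")
        counts = np.zeros((len(participants), len(concepts), 11), dtype=int)
        seen = np.zeros((len(participants), len(concepts)), dtype=bool)
        p_idx = {p: i for i, p in enumerate(participants)}
        c_idx = {c: i for i, c in enumerate(concepts)}
        for p, c, k, n in df.itertuples(index=False):
            counts[p_idx[p], c_idx[c], cat_idx[k]] = n
            seen[p_idx[p], c_idx[c]] = True
        missing = {
            (p, c)
            for p in participants
            for c in concepts
            if not seen[p_idx[p], c_idx[c]]
        }
        return cls(participants=participants, concepts=concepts,
                   counts=counts, missing=missing)


@dataclass(frozen=True)
class EventDesign:
    """Event onsets/durations/conditions for one run, in seconds."""

    onsets: np.ndarray = field(repr=False)
    durations: np.ndarray = field(repr=False)
    conditions: np.ndarray = field(repr=False)
    run_length: float
    tr: float

    def __post_init__(self):
        on = np.asarray(self.onsets, dtype=float)
        du = np.asarray(self.durations, dtype=float)
        co = np.asarray(self.conditions, dtype=object)
        if not (on.shape == du.shape == co.shape):
            raise ValueError("onsets, durations, conditions must align")
        if on.size and np.any(np.diff(on) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if on.size and np.any(on + du > self.run_length + 1e-9):
            raise ValueError("events must end within the run")
        object.__setattr__(self, "onsets", on)
        object.__setattr__(self, "durations", du)
        object.__setattr__(self, "conditions", co)

    @property
    def n_events(self) -> int:
        return self.onsets.size

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"onset": self.onsets, "duration": self.durations,
             "condition": self.conditions}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, tr: float = DEFAULT_TR,
                 run_length: float | None = None) -> "EventDesign":
        df = pd.read_csv(path, sep="\t")
        need = {"onset", "duration", "condition"}
        if not need.issubset(df.columns):
            raise ValueError(f"{path}: columns {sorted(need)} required")
        if run_length is None:
            end = float((df["onset"] + df["duration"]).max())
            run_length = math.ceil((end + 16.0) / tr) * tr
        return cls(
            onsets=df["onset"].to_numpy(float),
            durations=df["duration"].to_numpy(float),
            conditions=df["condition"].to_numpy(object),
            run_length=run_length,
            tr=tr,
        )


@dataclass(frozen=True)
class VolumeSeries:
    """4-D BOLD grid (x, y, z, t) with voxel size, binary mask, and TR."""

    data: np.ndarray = field(repr=False)
    voxel_size: tuple
    mask: np.ndarray = field(repr=False)
    tr: float

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if data.ndim != 4:
            raise ValueError("data must be 4-D (x, y, z, t)")
        if mask.shape != data.shape[:3]:
            raise ValueError("mask shape must equal the spatial data shape")
        if not mask.any():
            raise ValueError("mask must contain at least one voxel")
        vs = tuple(float(v) for v in np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)))
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "voxel_size", vs)

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
        return aff

    def to_nifti(self):
        bold = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        bold.header.set_zooms(self.voxel_size + (self.tr,))
        mask = nib.Nifti1Image(self.mask.astype(np.uint8), self.affine)
        return bold, mask

    @classmethod
    def from_nifti(cls, bold_path, mask_path, tr: float | None = None
                   ) -> "VolumeSeries":
        bold = nib.load(str(bold_path))
        mask = nib.load(str(mask_path))
        zooms = bold.header.get_zooms()
        if tr is None:
            tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else DEFAULT_TR
        return cls(
            data=np.asarray(bold.dataobj, dtype=float),
            voxel_size=zooms[:3],
            mask=np.asarray(mask.dataobj) > 0,
            tr=tr,
        )


@dataclass(frozen=True)
class PatternSet:
    """Ground-truth activation patterns over a set of ROI voxels.

    ``roi_indices`` are linear (C-order) indices into the flattened 3-D
    grid; ``patterns`` has one row per concept and one column per ROI
    voxel.
    """

    concepts: tuple
    patterns: np.ndarray = field(repr=False)
    roi_indices: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "concepts", tuple(self.concepts))
        p = np.asarray(self.patterns, dtype=float)
        idx = np.asarray(self.roi_indices, dtype=int)
        if p.shape != (len(self.concepts), idx.size):
            raise ValueError("patterns must be concepts x roi voxels")
        object.__setattr__(self, "patterns", p)
        object.__setattr__(self, "roi_indices", idx)


# ---------------------------------------------------------------------------
# masks and ROIs

def ellipsoid_mask(shape=(20, 20, 20), semiaxes=None) -> np.ndarray:
    """Ellipsoidal brain-like mask centered in a 3-D grid.

    Default semiaxes are 45% of each grid dimension, leaving a rim of
    out-of-mask voxels so radius-3 searchlights meet the boundary.
    """
    shape = tuple(int(s) for s in shape)
    if semiaxes is None:
        semiaxes = tuple(0.45 * s for s in shape)
    center = [(s - 1) / 2.0 for s in shape]
    grids = np.indices(shape).astype(float)
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return r2 <= 1.0


def ball_roi(mask: np.ndarray, center, n_voxels: int) -> np.ndarray:
    """Linear indices of the ``n_voxels`` in-mask voxels nearest ``center``.

    A compact quasi-spherical ROI of exact size; ties in distance are broken
    by linear index so the result is deterministic.
    """
    mask = np.asarray(mask, dtype=bool)
    flat = np.flatnonzero(mask)
    if n_voxels > flat.size:
        raise ValueError("ROI larger than the mask")
    coords = np.array(np.unravel_index(flat, mask.shape)).T.astype(float)
    d2 = np.sum((coords - np.asarray(center, dtype=float)) ** 2, axis=1)
    order = np.lexsort((flat, d2))
    return np.sort(flat[order[:n_voxels]])


# ---------------------------------------------------------------------------
# generators

def make_semantic_space(
    n_concepts: int = 58,
    n_dims: int = 400,
    n_latent: int = 5,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> SemanticMatrix:
    """Latent-factor stand-in for a distributional word-embedding space.

    Each concept vector is a linear mixture of ``n_latent`` latent factors
    plus isotropic Gaussian noise, so concepts have a controllable low-rank
    similarity structure like co-occurrence embeddings do.
    """
    if n_concepts < 2 or n_dims < 1:
        raise ValueError("need at least 2 concepts and 1 dimension")
    if not 1 <= n_latent <= n_dims:
        raise ValueError("need 1 <= n_latent <= n_dims")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    scores = rng.standard_normal((n_concepts, n_latent))
    loadings = rng.standard_normal((n_latent, n_dims))
    vectors = scores @ loadings
    if noise_sd > 0:
        vectors = vectors + noise_sd * rng.standard_normal(vectors.shape)
    labels = [f"concept_{i:03d}" for i in range(n_concepts)]
    return SemanticMatrix(concepts=labels, vectors=vectors)


def make_property_listings(
    n_participants: int = 51,
    n_concepts: int = 58,
    mean_props: float = 3.5,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> PropertyListings:
    """Simulate property-listing category counts.

    Participants list on average ``mean_props`` properties per concept
    (zero-truncated Poisson total), distributed over the 11 feature
    categories according to a concept-specific category profile shared
    across participants (so concepts carry a recoverable experiential
    signature).  Each (participant, concept) cell is independently flagged
    missing with probability ``missing_rate``.
    """
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    if mean_props <= 0:
        raise ValueError("mean_props must be positive")
    rng = np.random.default_rng(seed)
    participants = [f"P{i:02d}" for i in range(n_participants)]
    concepts = [f"concept_{i:03d}" for i in range(n_concepts)]
    profiles = rng.dirichlet(np.full(11, 0.6), size=n_concepts)
    counts = np.zeros((n_participants, n_concepts, 11), dtype=int)
    missing = set()
    for pi, p in enumerate(participants):
        for ci, c in enumerate(concepts):
            if rng.random() < missing_rate:
                missing.add((p, c))
                continue
            total = int(rng.poisson(mean_props))
            if total == 0:
                total = 1
            counts[pi, ci] = rng.multinomial(total, profiles[ci])
    return PropertyListings(participants=participants, concepts=concepts,
                            counts=counts, missing=missing)


def draw_itis(n: int, mean_ms: float = 3173.0, sd_ms: float = 3435.0,
              rng=None) -> np.ndarray:
    """Draw intertrial intervals (seconds) from a right-skewed distribution.

    A gamma distribution matched to the stated mean and SD (zero-truncated
    by construction) emulates the skewed jitter distribution of an
    optimized rapid event-related sequence.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    mean = mean_ms / 1000.0
    sd = sd_ms / 1000.0
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return rng.gamma(shape, scale, size=n)


def sequence_ok(labels: Sequence, max_run: int) -> bool:
    """True iff no label repeats more than ``max_run`` consecutive times."""
    run = 0
    prev = object()
    for lab in labels:
        run = run + 1 if lab == prev else 1
        prev = lab
        if run > max_run:
            return False
    return True


def _constrained_sequence(counts: Mapping, max_run: int, rng) -> list:
    labels = list(counts)
    remaining = dict(counts)
    total = sum(remaining.values())
    biggest = max(remaining.values())
    if biggest > max_run * (total - biggest + 1):
        raise ValueError(
            f"no sequence with counts {dict(counts)} satisfies max_run={max_run}"
        )
    for _ in range(1000):  # restart on dead ends
        rem = dict(remaining)
        seq = []
        run_label, run_len = None, 0
        ok = True
        while len(seq) < total:
            allowed = [
                lab for lab in labels
                if rem[lab] > 0 and not (lab == run_label and run_len >= max_run)
            ]
            if not allowed:
                ok = False
                break
            w = np.array([rem[lab] for lab in allowed], dtype=float)
            lab = allowed[rng.choice(len(allowed), p=w / w.sum())]
            seq.append(lab)
            rem[lab] -= 1
            run_len = run_len + 1 if lab == run_label else 1
            run_label = lab
        if ok:
            return seq
    raise RuntimeError("failed to sample a constrained sequence")


def make_event_design(
    n_per_cond: Mapping | None = None,
    trial_ms: float = 2400.0,
    iti_mean_ms: float = 3173.0,
    iti_sd_ms: float = 3435.0,
    max_run: int = 3,
    tr: float = DEFAULT_TR,
    seed: int = 0,
) -> EventDesign:
    """Jittered rapid event-related design like the lexical decision task.

    Defaults emulate the study: 64 word and 64 pseudoword trials of 2400 ms
    each, intertrial intervals averaging 3173 ms from a right-skewed
    distribution, no condition recurring more than three consecutive times,
    and onsets jittered by random sub-TR fractions.
    """
    if n_per_cond is None:
        n_per_cond = {"word": 64, "pseudoword": 64}
    if max_run < 1:
        raise ValueError("max_run must be >= 1")
    if trial_ms <= 0:
        raise ValueError("trial_ms must be positive")
    rng = np.random.default_rng(seed)
    seq = _constrained_sequence(n_per_cond, max_run, rng)
    n = len(seq)
    trial = trial_ms / 1000.0
    itis = draw_itis(n, iti_mean_ms, iti_sd_ms, rng)
    base = 2 * tr + np.concatenate([[0.0], np.cumsum(trial + itis[:-1])])
    onsets = base + rng.random(n) * tr  # sub-TR jitter
    if np.any(np.diff(onsets) <= 0):
        raise ValueError(
            "sub-TR jitter would reorder onsets (trial shorter than TR?)"
        )
    end = onsets[-1] + trial
    run_length = math.ceil((end + 16.0) / tr) * tr
    return EventDesign(
        onsets=onsets,
        durations=np.full(n, trial),
        conditions=np.array(seq, dtype=object),
        run_length=run_length,
        tr=tr,
    )


#: fixed localizer block timings (seconds): (n_blocks or labels, task, rest)
_BLOCK_PROTOCOLS = {
    "visual": {"labels": ["visual"] * 6, "task_s": 24.0, "rest_s": 27.8},
    "motor": {"labels": ["motor"] * 8, "task_s": 26.0, "rest_s": 26.0},
    "emotional": {
        "labels": ["neutral", "emotional"] * 6,
        "task_s": 23.8,
        "rest_s": 5.8,
    },
}


def make_block_design(protocol: str, tr: float = DEFAULT_TR) -> EventDesign:
    """Fixed block timing of one of the three localizer protocols.

    ``visual``: 6 picture-viewing blocks of 24 s separated by 27.8 s rests.
    ``motor``: 8 hand-movement blocks of 26 s alternating with 26 s rests.
    ``emotional``: 12 scene blocks of 23.8 s (6 emotional, 6 neutral,
    interleaved) separated by 5.8 s fixation.
    """
    if protocol not in _BLOCK_PROTOCOLS:
        raise ValueError(
            f"unknown protocol {protocol!r}; choose from "
            f"{sorted(_BLOCK_PROTOCOLS)}"
        )
    p = _BLOCK_PROTOCOLS[protocol]
    labels = p["labels"]
    onsets = []
    t = p["rest_s"]  # lead-in rest
    for _ in labels:
        onsets.append(t)
        t += p["task_s"] + p["rest_s"]
    end = onsets[-1] + p["task_s"]
    run_length = math.ceil((end + 16.0) / tr) * tr
    return EventDesign(
        onsets=np.array(onsets),
        durations=np.full(len(labels), p["task_s"]),
        conditions=np.array(labels, dtype=object),
        run_length=run_length,
        tr=tr,
    )


def assign_stimuli(design: EventDesign, condition: str,
                   labels: Sequence, seed: int = 0) -> EventDesign:
    """Randomly allocate stimulus labels to the trials of one condition.

    Mirrors the study's randomization: the trial sequence is fixed but each
    participant's stimuli are shuffled over the condition's trial slots, so
    each event of ``condition`` is relabelled with a unique stimulus label.
    """
    rng = np.random.default_rng(seed)
    idx = np.flatnonzero(np.asarray(design.conditions, dtype=object) == condition)
    if idx.size != len(labels):
        raise ValueError(
            f"{idx.size} trials of {condition!r} but {len(labels)} labels"
        )
    new = np.array(design.conditions, dtype=object)
    new[idx] = np.array(list(labels), dtype=object)[rng.permutation(idx.size)]
    return EventDesign(onsets=design.onsets, durations=design.durations,
                       conditions=new, run_length=design.run_length,
                       tr=design.tr)


#: default group-level correlation matrix for grouped planting targets;
#: PSD, with well-separated off-diagonal values so that the rank order of
#: RDM cells is stable under voxel subsampling
_GROUP_CORR = np.array([
    [1.00, 0.75, 0.35, -0.15],
    [0.75, 1.00, 0.55, 0.15],
    [0.35, 0.55, 1.00, -0.45],
    [-0.15, 0.15, -0.45, 1.00],
])


def grouped_rdm(n_conditions: int, n_groups: int = 4,
                group_corr: np.ndarray | None = None,
                labels: Sequence | None = None) -> RDM:
    """Block-structured RDM: conditions in the same group are identical.

    Conditions are split into ``n_groups`` near-equal groups; the distance
    between two conditions depends only on their groups (``1 - C[g, g']``
    with ``C`` a group-level correlation matrix, unit diagonal).  Because
    every cell value is shared by its whole group pair, the rank structure
    of the RDM survives restriction to arbitrary voxel subsets when the
    geometry is planted with :func:`embed_geometry`, making this the target
    of choice for exact end-to-end identity checks.
    """
    if group_corr is None:
        group_corr = _GROUP_CORR[:n_groups, :n_groups]
    group_corr = np.asarray(group_corr, dtype=float)
    if group_corr.shape != (n_groups, n_groups):
        raise ValueError("group_corr must be n_groups x n_groups")
    evals = np.linalg.eigvalsh(group_corr)
    if evals.min() < -1e-10:
        raise ValueError("group_corr must be positive semidefinite")
    if labels is None:
        labels = [f"concept_{i:03d}" for i in range(n_conditions)]
    group = np.arange(n_conditions) % n_groups
    d = 1.0 - group_corr[np.ix_(group, group)]
    np.fill_diagonal(d, 0.0)
    return RDM(labels=labels, d=d)


def embed_geometry(
    target: RDM,
    n_voxels: int,
    roi_indices: Sequence[int],
    amplitude: float = 1.0,
    seed: int = 0,
) -> PatternSet:
    """Construct activation patterns whose correlation RDM equals ``target``.

    The similarity matrix ``S = 1 - d`` (unit diagonal) is eigen-factorized
    and mixed with centered, orthonormal voxel basis vectors; the returned
    patterns therefore have sample correlation matrix exactly ``S`` across
    the ROI voxels, hence correlation-distance RDM exactly ``target``.
    Targets whose ``S`` is not positive semidefinite are not realizable as
    a correlation structure and are rejected.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    roi_indices = np.asarray(roi_indices, dtype=int)
    if n_voxels != roi_indices.size:
        raise ValueError("n_voxels must equal len(roi_indices)")
    k = target.n_conditions
    if n_voxels < k + 1:
        raise ValueError("need n_voxels >= n_conditions + 1")
    s = 1.0 - target.d
    np.fill_diagonal(s, 1.0)
    evals, evecs = np.linalg.eigh(s)
    if evals.min() < -1e-8:
        raise ValueError(
            f"target RDM is not correlation-realizable (min eigenvalue "
            f"{evals.min():.3g} < 0)"
        )
    keep = evals > 1e-10
    a = evecs[:, keep] * np.sqrt(np.clip(evals[keep], 0, None))  # k x r
    r = a.shape[1]
    rng = np.random.default_rng(seed)
    for _ in range(10):
        g = rng.standard_normal((n_voxels, r))
        g -= g.mean(axis=0)
        q, rr = np.linalg.qr(g)
        if np.abs(np.diag(rr)).min() > 1e-10:
            break
    else:  # pragma: no cover - essentially impossible
        raise RuntimeError("failed to draw a full-rank voxel basis")
    patterns = amplitude * (a @ q.T)
    return PatternSet(concepts=target.labels, patterns=patterns,
                      roi_indices=roi_indices)


def ar1_noise(n_time: int, n_series: int, phi: float, sd: float,
              rng=None) -> np.ndarray:
    """Stationary AR(1) Gaussian noise, shape (n_time, n_series).

    Marginal standard deviation ``sd`` and lag-1 autocorrelation ``phi``.
    """
    if not -1 < phi < 1:
        raise ValueError("ar1 phi must lie in (-1, 1)")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    out = np.empty((n_time, n_series))
    out[0] = rng.normal(0.0, sd, n_series)
    innov_sd = sd * math.sqrt(1.0 - phi * phi)
    for t in range(1, n_time):
        out[t] = phi * out[t - 1] + rng.normal(0.0, innov_sd, n_series)
    return out


def simulate_bold(
    design: EventDesign,
    patterns: PatternSet | None,
    shape=(20, 20, 20),
    voxel_size=(2.0, 2.0, 2.0),
    noise_sd: float = 1.0,
    ar1_phi: float = 0.0,
    motion: bool = False,
    mask: np.ndarray | None = None,
    seed: int = 0,
) -> VolumeSeries:
    """Simulate a 4-D BOLD series with a planted representational geometry.

    In-ROI voxel time courses are the HRF-convolved event regressors of the
    pattern concepts scaled by each voxel's pattern value; all in-mask
    voxels additionally receive stationary AR(1) Gaussian noise (out-of-ROI
    voxels contain noise only).  ``motion=True`` adds slow drifting
    nuisance components with random per-voxel weights.  The regressors are
    built by the same construction the GLM module fits with, so a
    zero-noise simulation is exactly reproduced by least squares.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape)
    if mask is None:
        mask = ellipsoid_mask(shape)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError("mask shape must equal the requested grid shape")
    tr = design.tr
    n_vols = int(round(design.run_length / tr))
    if design.onsets.size and design.onsets[-1] + design.durations[-1] > n_vols * tr:
        raise ValueError("design does not fit in the implied series length")

    flat = np.zeros((shape[0] * shape[1] * shape[2], n_vols))
    mask_flat = mask.reshape(-1)
    if patterns is not None:
        if not mask_flat[patterns.roi_indices].all():
            raise ValueError("roi_indices must lie within the mask")
        x = glm.task_regressors(design, patterns.concepts, n_vols, tr)
        flat[patterns.roi_indices] += (x @ patterns.patterns).T
    n_in = int(mask_flat.sum())
    if noise_sd > 0:
        flat[mask_flat] += ar1_noise(n_vols, n_in, ar1_phi, noise_sd, rng).T
    if motion:
        t = np.arange(n_vols) / n_vols
        drift_tc = np.column_stack(
            [np.cos(2 * np.pi * k * t + rng.uniform(0, 2 * np.pi))
             for k in (1, 2, 3)]
        )
        weights = rng.normal(0.0, 0.5 * (noise_sd or 1.0), (3, n_in))
        flat[mask_flat] += (drift_tc @ weights).T
    data = flat.reshape(shape + (n_vols,))
    return VolumeSeries(data=data, voxel_size=voxel_size, mask=mask, tr=tr)


# ---------------------------------------------------------------------------
# stimulus construction

def generate_pseudoword(word: str, seed: int = 0) -> str:
    """Derive a pseudoword by swapping exactly one vowel and one consonant.

    The output has the same length as the input and differs from it at
    exactly two positions: one vowel replaced by a different vowel and one
    consonant replaced by a different consonant (German inventory, umlauts
    counted as vowels; case is preserved).
    """
    rng = np.random.default_rng(seed)
    chars = list(word)
    vowel_pos = [i for i, ch in enumerate(chars) if ch.lower() in VOWELS]
    cons_pos = [
        i for i, ch in enumerate(chars)
        if ch.isalpha() and ch.lower() not in VOWELS
    ]
    if not vowel_pos or not cons_pos:
        raise ValueError(
            f"{word!r} needs at least one vowel and one consonant"
        )

    def replace(pos_list, alphabet):
        i = pos_list[rng.integers(len(pos_list))]
        old = chars[i]
        choices = [c for c in alphabet if c != old.lower()]
        new = choices[rng.integers(len(choices))]
        chars[i] = new.upper() if old.isupper() else new

    replace(vowel_pos, sorted(VOWELS))
    replace(cons_pos, _CONSONANTS)
    return "".join(chars)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


def length_match_test(lengths_a: Sequence[int],
                      lengths_b: Sequence[int]) -> TTestResult:
    """Pooled-variance two-sample t-test on stimulus lengths.

    Used to check that words and pseudowords are matched on letter count;
    ``df = n_a + n_b - 2``.  With zero pooled variance and equal means the
    statistic is 0 by convention.
    """
    a = np.asarray(lengths_a, dtype=float)
    b = np.asarray(lengths_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 entries per group")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, df=df, p=1.0)
        return TTestResult(t=math.inf * np.sign(a.mean() - b.mean()),
                           df=df, p=0.0)
    res = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(t=float(res.statistic), df=df, p=float(res.pvalue))
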