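"""Ground-truthed synthetic scenes and dilution series.

The analyses in this package assume a particular statistical structure:
nuclei arranged in space with controllable cohesion, per-nucleus marker
intensities drawn from a two-component (negative/positive) mixture, and
additive voxel noise on top. This module generates exactly that structure —
ellipsoidal nuclei rasterised into a 3D label mask with anisotropic voxels,
painted intensity channels, and a truth table recording every latent value —
so each downstream estimator can be tested against known ground truth.

Two placement regimes bracket the biology of interest: a hard-core process
(minimum centre separation, emulating cohesive colonies at controlled
spacing) and a Thomas cluster process (parent-centred Gaussian clumps,
emulating small dispersed clusters). No point-spread function or optical
attenuation is modelled: downstream consumers read per-nucleus means, not
raw optics, so intensities live on an arbitrary linear scale.

A synthetic RPPA generator with multiplicative spot noise complements the
imaging scenes.

Randomness: one seed per scene; placement, nuclear shapes, per-channel
class assignment and per-channel voxel noise each consume an independent
substream derived deterministically from it, so regenerating any part of a
scene is bit-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .io_core import IntensityStack, LabelMask, write_mask, write_stack, write_table
from .rppa import DilutionSeries

logger = logging.getLogger(__name__)

__all__ = [
    "ChannelSpec",
    "HardCore",
    "ThomasCluster",
    "SceneSpec",
    "GroundTruth",
    "InfeasiblePackingError",
    "sample_centres",
    "render_scene",
    "paint_channels",
    "make_scene",
    "write_scene",
    "simulate_rppa",
]


class InfeasiblePackingError(RuntimeError):
    """Hard-core placement gave up: too many points for the separation."""


@dataclass
class ChannelSpec:
    """Two-component intensity mixture for one marker channel.

    A nucleus is positive with probability ``positive_fraction``; its true
    mean intensity is drawn from N(pos_mean, pos_sd²) or N(neg_mean,
    neg_sd²) accordingly (clipped at zero). ``noise_sd`` is the SD of the
    additive i.i.d. voxel noise; background voxels carry noise only.
    """

    name: str
    positive_fraction: float = 0.5
    neg_mean: float = 100.0
    neg_sd: float = 10.0
    pos_mean: float = 300.0
    pos_sd: float = 20.0
    noise_sd: float = 20.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must lie in [0, 1]")
        for attr in ("neg_sd", "pos_sd", "noise_sd"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")


@dataclass
class HardCore:
    """Placement with a minimum allowed centre separation (µm)."""

    min_centre_sep_um: float = 10.0

    def __post_init__(self) -> None:
        if self.min_centre_sep_um < 0:
            raise ValueError("min_centre_sep_um must be >= 0")


@dataclass
class ThomasCluster:
    """Parent points with Gaussian-displaced offspring (µm dispersion)."""

    n_parents: int = 5
    dispersion_um: float = 15.0

    def __post_init__(self) -> None:
        if self.n_parents < 1:
            raise ValueError("n_parents must be >= 1")
        if self.dispersion_um <= 0:
            raise ValueError("dispersion_um must be > 0")


Placement = Union[HardCore, ThomasCluster]


@dataclass
class SceneSpec:
    """Full description of one synthetic scene.

    Extents and voxel sizes are (z, y, x) in µm; the z pitch is typically
    the coarsest, as in confocal stacks. A 2D scene is a single-slice 3D
    grid (domain z extent equal to the z voxel size).
    """

    domain_size_um: tuple[float, float, float] = (30.0, 200.0, 200.0)
    voxel_size_um: tuple[float, float, float] = (2.0, 1.0, 1.0)
    n_nuclei: int = 200
    placement: Placement = field(default_factory=HardCore)
    nucleus_radii_um: tuple[float, float, float] = (3.0, 4.0, 4.0)
    radius_jitter: float = 0.15
    channels: list[ChannelSpec] = field(default_factory=list)
    seed: int = 0
    replicate_id: str = "R1"
    image_id: str = "scene"

    def __post_init__(self) -> None:
        self.domain_size_um = tuple(float(v) for v in self.domain_size_um)
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        self.nucleus_radii_um = tuple(float(v) for v in self.nucleus_radii_um)
        if len(self.domain_size_um) != 3 or len(self.voxel_size_um) != 3:
            raise ValueError("domain_size_um and voxel_size_um must be 3-vectors")
        if any(v <= 0 for v in self.domain_size_um + self.voxel_size_um):
            raise ValueError("physical extents and voxel sizes must be > 0")
        if any(r <= 0 for r in self.nucleus_radii_um):
            raise ValueError("nucleus semi-axes must be > 0")
        if not 0.0 <= self.radius_jitter < 1.0:
            raise ValueError("radius_jitter must lie in [0, 1)")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(
            int(np.ceil(d / v))
            for d, v in zip(self.domain_size_um, self.voxel_size_um)
        )

    # -- JSON round trip (CLI configs) ------------------------------------

    def to_dict(self) -> dict:
        placement: dict
        if isinstance(self.placement, HardCore):
            placement = {
                "type": "hard_core",
                "min_centre_sep_um": self.placement.min_centre_sep_um,
            }
        else:
            placement = {
                "type": "thomas_cluster",
                "n_parents": self.placement.n_parents,
                "dispersion_um": self.placement.dispersion_um,
            }
        return {
            "domain_size_um": list(self.domain_size_um),
            "voxel_size_um": list(self.voxel_size_um),
            "n_nuclei": self.n_nuclei,
            "placement": placement,
            "nucleus_radii_um": list(self.nucleus_radii_um),
            "radius_jitter": self.radius_jitter,
            "channels": [vars(c).copy() for c in self.channels],
            "seed": self.seed,
            "replicate_id": self.replicate_id,
            "image_id": self.image_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        d = dict(d)
        p = dict(d.pop("placement", {"type": "hard_core"}))
        kind = p.pop("type")
        if kind == "hard_core":
            placement: Placement = HardCore(**p)
        elif kind == "thomas_cluster":
            placement = ThomasCluster(**p)
        else:
            raise ValueError(f"unknown placement type {kind!r}")
        channels = [ChannelSpec(**c) for c in d.pop("channels", [])]
        return cls(placement=placement, channels=channels, **d)


@dataclass
class GroundTruth:
    """Latent per-nucleus truth for a rendered scene.

    ``nuclei`` has one row per label actually present in the mask: centre,
    (jittered) semi-axes, and per channel the true class (``class_<name>``)
    and true mean intensity (``true_mean_<name>``).
    """

    nuclei: pd.DataFrame
    spec: SceneSpec

    @property
    def labels(self) -> np.ndarray:
        return self.nuclei["label"].to_numpy()


# ---------------------------------------------------------------------------
# RNG plumbing — fixed substream layout so stages can be re-run independently.


def _streams(spec: SceneSpec):
    root = np.random.SeedSequence(spec.seed)
    placement_ss, shapes_ss, channels_ss = root.spawn(3)
    per_channel = channels_ss.spawn(max(len(spec.channels), 1))
    channel_streams = [ss.spawn(2) for ss in per_channel]  # (class, noise)
    return placement_ss, shapes_ss, channel_streams


# ---------------------------------------------------------------------------
# Placement


def sample_centres(spec: SceneSpec) -> np.ndarray:
    """Nucleus centres (n, 3) in µm, inside the domain, per the placement.

    Hard-core placement uses rejection sampling with a bounded attempt
    budget; an infeasible request (too dense for the separation) raises
    :class:`InfeasiblePackingError` naming the attempted density rather
    than looping forever.
    """
    placement_ss, _, _ = _streams(spec)
    rng = np.random.default_rng(placement_ss)
    domain = np.asarray(spec.domain_size_um)
    n = spec.n_nuclei
    if n == 0:
        return np.empty((0, 3), dtype=float)

    if isinstance(spec.placement, HardCore):
        sep2 = spec.placement.min_centre_sep_um**2
        accepted = np.empty((n, 3), dtype=float)
        k = 0
        budget = max(10_000, 300 * n)
        attempts = 0
        while k < n:
            if attempts >= budget:
                vol = float(np.prod(domain))
                raise InfeasiblePackingError(
                    f"could not place {n} centres with min separation "
                    f"{spec.placement.min_centre_sep_um} µm in a "
                    f"{tuple(domain)} µm domain "
                    f"({n / vol:.2e} nuclei/µm³) after {attempts} attempts"
                )
            attempts += 1
            p = rng.uniform(0.0, domain)
            if k == 0 or (((accepted[:k] - p) ** 2).sum(axis=1) >= sep2).all():
                accepted[k] = p
                k += 1
        return accepted

    placement = spec.placement
    parents = rng.uniform(0.0, domain, size=(placement.n_parents, 3))
    assignment = rng.integers(0, placement.n_parents, size=n)
    offsets = rng.normal(0.0, placement.dispersion_um, size=(n, 3))
    pts = parents[assignment] + offsets
    return np.clip(pts, 0.0, domain)


# ---------------------------------------------------------------------------
# Rendering


def render_scene(centres, spec: SceneSpec) -> tuple[LabelMask, GroundTruth]:
    """Rasterise ellipsoidal nuclei into an integer label mask.

    Nucleus ``i`` (labels start at 1, in centre order) occupies the voxels
    whose centres fall inside its jittered axis-aligned ellipsoid; where
    ellipsoids overlap, each voxel goes to the nucleus with the smallest
    scaled centre distance, keeping the mask a valid partition. The truth
    table draws each channel's class and true mean here, so a mask and its
    truth are a single reproducible unit.
    """
    centres = np.asarray(centres, dtype=float).reshape(-1, 3)
    domain = np.asarray(spec.domain_size_um)
    if centres.size and (
        (centres < 0).any() or (centres > domain).any()
    ):
        raise ValueError("centres must lie inside the domain")
    _, shapes_ss, channel_streams = _streams(spec)
    shape_rng = np.random.default_rng(shapes_ss)
    pitch = np.asarray(spec.voxel_size_um)
    shape = spec.grid_shape
    n = len(centres)

    base = np.asarray(spec.nucleus_radii_um)
    jitter = shape_rng.uniform(-spec.radius_jitter, spec.radius_jitter, size=(n, 3))
    semi_axes = base * (1.0 + jitter)

    labels_grid = np.zeros(shape, dtype=np.int32)
    best_d2 = np.full(shape, np.inf, dtype=np.float64)
    for i in range(n):
        c, a = centres[i], semi_axes[i]
        lo = np.maximum(np.floor((c - a) / pitch - 0.5).astype(int), 0)
        hi = np.minimum(np.ceil((c + a) / pitch - 0.5).astype(int) + 1, shape)
        if (lo >= hi).any():
            raise ValueError(
                f"nucleus {i + 1} (centre {tuple(c)} µm) lies entirely "
                "outside the voxel grid"
            )
        axes_d = [
            ((np.arange(lo[ax], hi[ax]) + 0.5) * pitch[ax] - c[ax]) / a[ax]
            for ax in range(3)
        ]
        d2 = (
            (axes_d[0] ** 2)[:, None, None]
            + (axes_d[1] ** 2)[None, :, None]
            + (axes_d[2] ** 2)[None, None, :]
        )
        box = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        sel = (d2 <= 1.0) & (d2 < best_d2[box])
        labels_grid[box][sel] = i + 1
        best_d2[box][sel] = d2[sel]

    mask = LabelMask(
        voxels=labels_grid,
        voxel_size_um=spec.voxel_size_um,
        replicate_id=spec.replicate_id,
        image_id=spec.image_id,
    )

    rows = {
        "label": np.arange(1, n + 1, dtype=int),
        "centre_z_um": centres[:, 0],
        "centre_y_um": centres[:, 1],
        "centre_x_um": centres[:, 2],
        "semi_axis_z_um": semi_axes[:, 0],
        "semi_axis_y_um": semi_axes[:, 1],
        "semi_axis_x_um": semi_axes[:, 2],
    }
    truth = pd.DataFrame(rows)
    for ch, (class_ss, _) in zip(spec.channels, channel_streams):
        rng = np.random.default_rng(class_ss)
        positive = rng.random(n) < ch.positive_fraction
        means = np.where(
            positive,
            rng.normal(ch.pos_mean, ch.pos_sd, size=n),
            rng.normal(ch.neg_mean, ch.neg_sd, size=n),
        )
        truth[f"class_{ch.name}"] = positive
        truth[f"true_mean_{ch.name}"] = np.clip(means, 0.0, None)

    present = set(mask.labels.tolist())
    if len(present) < n:
        dropped = sorted(set(range(1, n + 1)) - present)
        logger.warning(
            "%d nuclei rendered no voxels (fully overlapped or sub-voxel) "
            "and were dropped from the truth table: %s",
            len(dropped),
            dropped[:10],
        )
        truth = truth[truth["label"].isin(present)].reset_index(drop=True)
    return mask, GroundTruth(nuclei=truth, spec=spec)


def paint_channels(
    mask: LabelMask, truth: GroundTruth, spec: SceneSpec
) -> IntensityStack:
    """Paint each channel: per-nucleus true mean plus i.i.d. voxel noise.

    Background voxels carry noise only; all values are clipped at zero so
    the stack satisfies the non-negativity contract.
    """
    if not spec.channels:
        raise ValueError("scene spec declares no channels to paint")
    truth_labels = set(truth.nuclei["label"].tolist())
    mask_labels = set(mask.labels.tolist())
    if truth_labels != mask_labels:
        raise ValueError("truth labels do not match mask labels")
    _, _, channel_streams = _streams(spec)
    max_label = int(mask.voxels.max()) if mask.voxels.size else 0
    channels: dict[str, np.ndarray] = {}
    for ch, (_, noise_ss) in zip(spec.channels, channel_streams):
        rng = np.random.default_rng(noise_ss)
        if ch.noise_sd > 0:
            img = rng.normal(0.0, ch.noise_sd, size=mask.shape)
        else:
            img = np.zeros(mask.shape, dtype=float)
        lut = np.zeros(max_label + 1, dtype=float)
        lut[truth.nuclei["label"].to_numpy()] = truth.nuclei[
            f"true_mean_{ch.name}"
        ].to_numpy()
        img += lut[mask.voxels]
        channels[ch.name] = np.clip(img, 0.0, None)
    return IntensityStack(channels=channels, voxel_size_um=spec.voxel_size_um)


def make_scene(spec: SceneSpec) -> tuple[LabelMask, IntensityStack | None, GroundTruth]:
    """Convenience: sample, render and (if channels are declared) paint."""
    centres = sample_centres(spec)
    mask, truth = render_scene(centres, spec)
    stack = paint_channels(mask, truth, spec) if spec.channels else None
    return mask, stack, truth


def write_scene(directory, mask, stack, truth) -> dict[str, Path]:
    """Persist a scene: mask + channels as TIFF, truth as CSV, spec as JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    out["mask"] = write_mask(mask, directory / "mask.tif")
    if stack is not None:
        for name, p in write_stack(stack, directory).items():
            out[f"channel_{name}"] = p
    out["truth"] = write_table(truth.nuclei, directory / "truth.csv")
    spec_path = directory / "scene_spec.json"
    spec_path.write_text(json.dumps(truth.spec.to_dict(), indent=2))
    out["spec"] = spec_path
    return out


# ---------------------------------------------------------------------------
# Synthetic RPPA


def simulate_rppa(
    slope_per_antibody: Mapping[str, float],
    rfi_truth: Mapping[str, Mapping[str, float]],
    n_dilutions: int = 4,
    n_spots: int = 3,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> list[DilutionSeries]:
    """Doubling dilution series with multiplicative spot noise.

    Spot intensity is ``rfi * factor**(-slope) * (1 + eps)`` with
    ``eps ~ N(0, noise_sd²)`` and factors 1, 2, 4, ... No additive
    background is modelled, matching the downstream fit which performs no
    background subtraction.
    """
    if n_dilutions < 2:
        raise ValueError("n_dilutions must be >= 2")
    if n_spots < 1:
        raise ValueError("n_spots must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    factors = 2.0 ** np.arange(n_dilutions)
    out: list[DilutionSeries] = []
    for antibody, samples in rfi_truth.items():
        slope = float(slope_per_antibody[antibody])
        for sample_id, rfi in samples.items():
            clean = float(rfi) * factors ** (-slope)
            eps = rng.normal(0.0, noise_sd, size=(n_dilutions, n_spots))
            intensities = np.clip(clean[:, None] * (1.0 + eps), 0.0, None)
            out.append(
                DilutionSeries(
                    antibody=antibody,
                    sample_id=str(sample_id),
                    intensities=intensities,
                    dilution_factors=tuple(factors),
                )
            )
    return out
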