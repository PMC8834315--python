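"""Seeded synthetic-data generators for every pipeline stage.

Each generator is a pure function of its spec (seed included): the same
spec reproduces bit-identical output. Ground-truth records carry enough
information to compute the expected downstream result without
re-inspecting pixels or lanes.

Generators:

* :func:`gen_filipin_field` — single-channel field with cells on a dark
  background and perinuclear puncta whose abundance is set by an
  accumulation parameter ``a``;
* :func:`gen_coloc_pair` — two channels with an exactly planted
  population correlation;
* :func:`gen_blot_dataset` — lane tables with planted fold changes and
  glycoform fractions under multiplicative lognormal noise;
* :func:`gen_screen_table` — a compound score table with a planted hit
  count at a reference energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GenerationError
from .imaging import ThresholdPair

__all__ = [
    "FilipinFieldSpec",
    "ColocSpec",
    "BlotSpec",
    "ScreenSpec",
    "gen_filipin_field",
    "gen_coloc_pair",
    "gen_blot_dataset",
    "gen_screen_table",
]

_RNG_NAME = "numpy.random.Generator(PCG64)"


@dataclass(frozen=True)
class FilipinFieldSpec:
    """Geometry and intensity model of one synthetic filipin field.

    Puncta sit in a perinuclear annulus at 0.3-0.6 of the cell radius.
    The number of puncta per cell is ``round(a * max_puncta_per_cell)``.
    """

    shape: tuple[int, int] = (128, 128)
    n_cells: int = 5
    cell_radius_range: tuple[float, float] = (12.0, 18.0)
    accumulation: float = 0.5  # a in [0, 1]
    punctum_intensity: float = 200.0
    punctum_radius: float = 1.5
    max_puncta_per_cell: int = 20
    baseline: float = 20.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.accumulation <= 1.0):
            raise GenerationError(f"accumulation must be in [0, 1], got {self.accumulation}")
        if self.baseline < 0 or self.punctum_intensity < 0 or self.noise_sd < 0:
            raise GenerationError("intensities and noise SD must be non-negative")
        if self.n_cells < 1 or self.max_puncta_per_cell < 1:
            raise GenerationError("need at least one cell and one punctum slot")
        lo, hi = self.cell_radius_range
        if not (0 < lo <= hi):
            raise GenerationError("invalid cell radius range")


def _disk_mask(shape: tuple[int, int], cy: float, cx: float, radius: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def gen_filipin_field(spec: FilipinFieldSpec) -> tuple[np.ndarray, dict]:
    """Render one field and return (image, ground-truth record).

    Cells are placed by rejection sampling without overlap; an infeasible
    packing raises GenerationError. Puncta pixels are set to
    ``baseline + punctum_intensity`` (assignment, so overlaps do not
    stack), which keeps the supra-threshold sum in closed form.

    Cell geometry, candidate punctum positions, and the noise field are
    drawn from independent child streams of the seed, so raising only
    ``accumulation`` adds puncta to an otherwise identical field.
    """
    h, w = spec.shape
    ss = np.random.SeedSequence(spec.seed)
    rng_cells, rng_puncta, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    lo, hi = spec.cell_radius_range
    cells: list[tuple[float, float, float]] = []  # (cy, cx, r)
    max_tries = 2000
    for _ in range(spec.n_cells):
        for _try in range(max_tries):
            r = float(rng_cells.uniform(lo, hi))
            cy = float(rng_cells.uniform(r, h - r))
            cx = float(rng_cells.uniform(r, w - r))
            if all((cy - y) ** 2 + (cx - x) ** 2 > (r + rr) ** 2 for y, x, rr in cells):
                cells.append((cy, cx, r))
                break
        else:
            raise GenerationError(
                f"could not place {spec.n_cells} non-overlapping cells in {spec.shape}"
            )

    image = np.zeros(spec.shape, dtype=float)
    cell_mask = np.zeros(spec.shape, dtype=bool)
    for cy, cx, r in cells:
        cell_mask |= _disk_mask(spec.shape, cy, cx, r)
    image[cell_mask] = spec.baseline

    # candidate puncta are drawn for every slot regardless of `a`; only the
    # first round(a * max) per cell are applied
    n_active = int(round(spec.accumulation * spec.max_puncta_per_cell))
    punctum_mask = np.zeros(spec.shape, dtype=bool)
    puncta_used: list[tuple[float, float]] = []
    for cy, cx, r in cells:
        radii = rng_puncta.uniform(0.3 * r, 0.6 * r, size=spec.max_puncta_per_cell)
        angles = rng_puncta.uniform(0, 2 * math.pi, size=spec.max_puncta_per_cell)
        for rad, ang in zip(radii[:n_active], angles[:n_active]):
            py = cy + rad * math.sin(ang)
            px = cx + rad * math.cos(ang)
            punctum_mask |= _disk_mask(spec.shape, py, px, spec.punctum_radius)
            puncta_used.append((py, px))
    punctum_mask &= cell_mask
    image[punctum_mask] = spec.baseline + spec.punctum_intensity

    clean_punctum_sum = float(image[punctum_mask].sum())
    n_cell_pixels = int(cell_mask.sum())
    n_punctum_pixels = int(punctum_mask.sum())

    if spec.noise_sd > 0:
        image = image + rng_noise.normal(0.0, spec.noise_sd, size=spec.shape)
        np.clip(image, 0.0, None, out=image)

    thresholds = ThresholdPair(
        t_low=spec.baseline / 2.0,
        t_high=spec.baseline + spec.punctum_intensity / 2.0,
    )
    truth = {
        "rng": _RNG_NAME,
        "seed": spec.seed,
        "cells": [(cy, cx, r) for cy, cx, r in cells],
        "n_puncta_per_cell": n_active,
        "puncta_centers": puncta_used,
        "n_cell_pixels": n_cell_pixels,
        "n_punctum_pixels": n_punctum_pixels,
        "clean_punctum_intensity_sum": clean_punctum_sum,
        "recommended_t_low": thresholds.t_low,
        "recommended_t_high": thresholds.t_high,
        "expected_noise_free_ratio": (
            clean_punctum_sum / n_cell_pixels if n_cell_pixels else 0.0
        ),
    }
    return image, truth


@dataclass(frozen=True)
class ColocSpec:
    """Two-channel pixel generator with planted population correlation."""

    rho: float = 0.8
    n_pixels: int = 10_000
    mean1: float = 100.0
    sd1: float = 20.0
    mean2: float = 80.0
    sd2: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (-1.0 <= self.rho <= 1.0):
            raise GenerationError(f"rho must be in [-1, 1], got {self.rho}")
        if self.n_pixels < 2:
            raise GenerationError("need at least 2 pixels")
        if self.sd1 <= 0 or self.sd2 <= 0:
            raise GenerationError("channel SDs must be > 0")


def gen_coloc_pair(spec: ColocSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate paired channels with population correlation exactly ``rho``.

    Construction: shared standard-normal latent Z plus independent noise,
    ``x_i = sqrt(|rho|)*Z + sqrt(1-|rho|)*E_i``; for negative rho the
    latent enters the second channel with flipped sign.
    """
    rng = np.random.default_rng(spec.seed)
    rho = abs(spec.rho)
    z = rng.standard_normal(spec.n_pixels)
    e1 = rng.standard_normal(spec.n_pixels)
    e2 = rng.standard_normal(spec.n_pixels)
    a, b = math.sqrt(rho), math.sqrt(1.0 - rho)
    x1 = a * z + b * e1
    x2 = (a if spec.rho >= 0 else -a) * z + b * e2
    ch1 = spec.mean1 + spec.sd1 * x1
    ch2 = spec.mean2 + spec.sd2 * x2
    return ch1, ch2


@dataclass(frozen=True)
class BlotSpec:
    """Planted blot experiment: per-condition fold changes and f_R fractions."""

    folds: dict[str, float] = field(
        default_factory=lambda: {"DMSO": 1.0, "MG132": 2.5}
    )
    fractions: dict[str, float] = field(
        default_factory=lambda: {"DMSO": 0.25, "MG132": 0.25}
    )
    control_condition: str = "DMSO"
    n_lanes: int = 4
    cv: float = 0.15
    control_level: float = 1.0  # npc1/actin ratio in the control condition
    actin_base: float = 1000.0
    glyco_total: float = 800.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.control_condition not in self.folds:
            raise GenerationError("control condition must appear in folds")
        if any(f <= 0 for f in self.folds.values()):
            raise GenerationError("planted folds must be > 0")
        if any(not (0.0 <= f <= 1.0) for f in self.fractions.values()):
            raise GenerationError("planted fractions must be in [0, 1]")
        if self.cv < 0 or self.n_lanes < 1:
            raise GenerationError("cv must be >= 0 and n_lanes >= 1")


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise with unit mean; exact ones when cv == 0."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def gen_blot_dataset(spec: BlotSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (lane table, glycoform table) for a planted experiment.

    Lane table columns: lane_id, condition, npc1_signal, actin_signal.
    Glycoform table columns: lane_id, condition, endoH_R, endoH_S.
    """
    rng = np.random.default_rng(spec.seed)
    lanes, glyco = [], []
    for cond, fold in spec.folds.items():
        actin = spec.actin_base * _lognormal_factor(rng, spec.cv, spec.n_lanes)
        level_noise = _lognormal_factor(rng, spec.cv, spec.n_lanes)
        npc1 = actin * spec.control_level * fold * level_noise
        f_r = spec.fractions.get(cond, 0.5)
        r_noise = _lognormal_factor(rng, spec.cv, spec.n_lanes)
        s_noise = _lognormal_factor(rng, spec.cv, spec.n_lanes)
        for i in range(spec.n_lanes):
            lane_id = f"{cond}_{i + 1}"
            lanes.append(
                {
                    "lane_id": lane_id,
                    "condition": cond,
                    "npc1_signal": float(npc1[i]),
                    "actin_signal": float(actin[i]),
                }
            )
            glyco.append(
                {
                    "lane_id": lane_id,
                    "condition": cond,
                    "endoH_R": float(spec.glyco_total * f_r * r_noise[i]),
                    "endoH_S": float(spec.glyco_total * (1.0 - f_r) * s_noise[i]),
                }
            )
    return pd.DataFrame(lanes), pd.DataFrame(glyco)


@dataclass(frozen=True)
class ScreenSpec:
    """Score table with a planted number of hits at/below a reference energy."""

    n_compounds: int = 1920
    n_hits: int = 10
    reference_energy: float = -11.3
    n_at_reference: int = 0  # hits planted exactly on the boundary
    hit_depth: float = 2.0  # hits span [reference - depth, reference]
    nonhit_gap: float = 0.05  # non-hits start this far above the reference
    nonhit_span: float = 6.0
    heavy_atom_range: tuple[int, int] = (15, 40)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_hits <= self.n_compounds):
            raise GenerationError("planted hit count must be <= n_compounds")
        if not (0 <= self.n_at_reference <= self.n_hits):
            raise GenerationError("boundary hits must be <= planted hits")
        if self.hit_depth <= 0 or self.nonhit_gap <= 0 or self.nonhit_span <= 0:
            raise GenerationError("energy spans must be > 0")


def gen_screen_table(spec: ScreenSpec) -> tuple[pd.DataFrame, dict]:
    """Generate a compound score table and its ground truth.

    Exactly ``n_hits`` rows have energy <= reference (``n_at_reference``
    of them exactly at it); all others are strictly above. Rows are
    shuffled; ground truth lists the planted hit ids.
    """
    rng = np.random.default_rng(spec.seed)
    ref = spec.reference_energy
    n_free_hits = spec.n_hits - spec.n_at_reference
    energies = np.concatenate(
        [
            np.full(spec.n_at_reference, ref),
            rng.uniform(ref - spec.hit_depth, ref - 1e-9, size=n_free_hits),
            rng.uniform(
                ref + spec.nonhit_gap,
                ref + spec.nonhit_gap + spec.nonhit_span,
                size=spec.n_compounds - spec.n_hits,
            ),
        ]
    )
    is_hit = np.zeros(spec.n_compounds, dtype=bool)
    is_hit[: spec.n_hits] = True
    order = rng.permutation(spec.n_compounds)
    energies, is_hit = energies[order], is_hit[order]
    lo, hi = spec.heavy_atom_range
    n_heavy = rng.integers(lo, hi + 1, size=spec.n_compounds)
    ids = [f"SYN{i:05d}" for i in range(spec.n_compounds)]
    table = pd.DataFrame(
        {
            "compound_id": ids,
            "name": [f"synthetic compound {i}" for i in range(spec.n_compounds)],
            "heavy_atoms": n_heavy,
            "binding_energy": np.round(energies, 4),
        }
    )
    # rounding must not move a non-hit across the boundary
    table.loc[~is_hit, "binding_energy"] = np.maximum(
        table.loc[~is_hit, "binding_energy"], ref + 1e-4
    )
    table.loc[is_hit, "binding_energy"] = np.minimum(
        table.loc[is_hit, "binding_energy"], ref
    )
    truth = {
        "rng": _RNG_NAME,
        "seed": spec.seed,
        "reference_energy": ref,
        "hit_ids": sorted(np.asarray(ids)[is_hit].tolist()),
        "n_hits": int(is_hit.sum()),
    }
    return table, truth
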