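"""Synthetic two-channel fluorescence microscopy fields with ground truth.

Emulates the imaging conditions of an oleic-acid lipid-droplet (LD) biogenesis
assay in adherent fibroblast-like cells (A431-style): channel 1 carries
DAPI-stained nuclei rendered as Gaussian-shaded ellipses, channel 2 carries
Bodipy-type neutral-lipid staining rendered as small bright Gaussian spots
clustered in the cytoplasm. Per-cell LD counts are Poisson with a
treatment-dependent rate; cytotoxicity is emulated as binomial thinning of the
nominal cell number. Everything is seeded and bit-reproducible, and every
rendered object is reported back as ground truth so that the segmentation and
screening layers can be validated against known answers.

Units: lengths in pixels, intensities in 16-bit grayscale units, rates in
LDs per cell, concentrations as given by the scenario (uM unless noted).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

__all__ = [
    "SceneParams",
    "SceneTruth",
    "ScenarioConfig",
    "UptakeKinetics",
    "PlateSpec",
    "PlacementError",
    "ScenarioError",
    "render_scene",
    "render_plate",
    "scenario_library",
    "screen_plate_scenario",
    "simulate_uptake_series",
]

MAX_UINT16 = 65535

# Calibrated regime constants: growth in delipidated serum leaves fewer than
# five droplets per cell, and oleic-acid loading raises the average roughly
# ten-fold. These two rates anchor every shipped scenario.
DELIPIDATED_RATE = 3.5
OLEIC_RATE = 35.0


class PlacementError(RuntimeError):
    """Raised when objects cannot be placed within the bounded retry budget."""


class ScenarioError(KeyError):
    """Raised when a plate-layout treatment cannot be resolved in a scenario."""


@dataclass(frozen=True)
class SceneParams:
    """Parameters of a single simulated field.

    ``ld_diameter_px`` is the FWHM range of the rendered Gaussian spots;
    ``ld_min_separation_px`` enforces a minimum centre-to-centre distance
    between droplets of the same cell (relaxed, then dropped, if a cell is too
    crowded to satisfy it). ``ld_margin_px`` keeps droplets away from the
    nucleus edge and from the territory boundary so that ground truth is not
    ambiguous at single-pixel resolution.
    """

    field_shape: Tuple[int, int] = (512, 512)
    n_cells: int = 30
    nucleus_radius_px: float = 12.0
    nucleus_radius_jitter_px: float = 2.0
    cytoplasm_radius_px: float = 40.0
    ld_rate: float = 20.0
    ld_diameter_px: Tuple[float, float] = (3.0, 8.0)
    ld_min_separation_px: float = 8.0
    ld_margin_px: float = 2.0
    ld_peak_intensity: float = 600.0
    nucleus_peak_intensity: float = 3000.0
    background_level: float = 100.0
    psf_sigma_px: float = 1.0
    noise_sd: float = 20.0
    cell_min_distance_px: Optional[float] = None
    seed: int = 0

    def validate(self) -> None:
        if self.nucleus_radius_px <= 0 or self.cytoplasm_radius_px <= 0:
            raise ValueError("radii must be positive")
        if self.ld_rate < 0:
            raise ValueError("ld_rate must be >= 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        lo, hi = self.ld_diameter_px
        if not (0 < lo <= hi):
            raise ValueError("ld_diameter_px must satisfy 0 < min <= max")
        if min(self.field_shape) < 4 * self.nucleus_radius_px and self.n_cells > 0:
            raise ValueError("field_shape too small for the requested nuclei")
        peak = self.background_level + self.nucleus_peak_intensity + self.ld_peak_intensity
        if peak > MAX_UINT16:
            raise ValueError("intensities exceed the 16-bit range")

    @property
    def min_center_distance(self) -> float:
        if self.cell_min_distance_px is not None:
            return self.cell_min_distance_px
        return 2.2 * self.nucleus_radius_px


@dataclass
class SceneTruth:
    """Ground truth for one rendered field.

    ``cells`` has one row per cell (cell_id, nuc_row, nuc_col, nuc_a, nuc_b,
    nuc_theta, ld_count); ``lds`` one row per planted droplet (cell_id, row,
    col, diameter_px, peak); ``territory_labels`` / ``nucleus_labels`` are the
    planted cytoplasm-territory and nucleus label maps (cell_id-valued).
    """

    cells: pd.DataFrame
    lds: pd.DataFrame
    territory_labels: np.ndarray
    nucleus_labels: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def mean_ld_count(self) -> float:
        if self.n_cells == 0:
            return float("nan")
        return float(self.cells["ld_count"].mean())


@dataclass(frozen=True)
class UptakeKinetics:
    """Saturating fatty-acid uptake: I(t) = i_max * (1 - exp(-t / tau_min))."""

    i_max: float = 100.0
    tau_min: float = 10.0 / 3.0  # plateau (95% of i_max) at 3*tau = 10 min

    def intensity(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.i_max * (1.0 - np.exp(-t / self.tau_min))


@dataclass(frozen=True)
class ScenarioConfig:
    """Treatment semantics: LD rate and cell survival per treatment label.

    Maps are keyed either by the bare treatment name (extract id or control
    role) or by ``"<name>:<concentration>"`` with the concentration formatted
    via ``format(conc, 'g')``; the concentration-qualified key wins.
    """

    name: str
    ld_rate_map: Dict[str, float]
    toxicity_map: Dict[str, float] = field(default_factory=dict)
    uptake: Optional[UptakeKinetics] = None

    def validate(self) -> None:
        for key, lam in self.ld_rate_map.items():
            if lam < 0:
                raise ValueError(f"negative LD rate for treatment {key!r}")
        for key, s in self.toxicity_map.items():
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"survival fraction for {key!r} outside [0, 1]")

    @staticmethod
    def _keys(treatment: str, concentration: Optional[float]) -> List[str]:
        keys = []
        if concentration is not None and np.isfinite(concentration):
            keys.append(f"{treatment}:{format(float(concentration), 'g')}")
        keys.append(treatment)
        return keys

    def ld_rate(self, treatment: str, concentration: Optional[float] = None) -> float:
        for key in self._keys(treatment, concentration):
            if key in self.ld_rate_map:
                return self.ld_rate_map[key]
        raise ScenarioError(
            f"treatment {treatment!r} (conc={concentration!r}) not in scenario {self.name!r}"
        )

    def survival(self, treatment: str, concentration: Optional[float] = None) -> float:
        for key in self._keys(treatment, concentration):
            if key in self.toxicity_map:
                return self.toxicity_map[key]
        return 1.0


@dataclass(frozen=True)
class PlateSpec:
    """One simulated plate: a layout, a scenario, and rendering parameters."""

    layout: pd.DataFrame
    scenario: ScenarioConfig
    fields_per_well: int = 1
    base_params: SceneParams = field(default_factory=SceneParams)
    seed: int = 0


# ---------------------------------------------------------------------------
# scene rendering


def _place_centers(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample nucleus centres with a minimum pairwise distance."""
    n = params.n_cells
    if n == 0:
        return np.zeros((0, 2))
    margin = params.nucleus_radius_px + params.nucleus_radius_jitter_px + 2.0
    rows, cols = params.field_shape
    if rows - 2 * margin <= 0 or cols - 2 * margin <= 0:
        raise PlacementError("field too small for nucleus placement margin")
    min_d2 = params.min_center_distance ** 2
    centers: List[np.ndarray] = []
    tries = 0
    max_tries = 200 * n
    while len(centers) < n:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {n} cells in field {params.field_shape} "
                f"after {max_tries} tries"
            )
        tries += 1
        cand = np.array(
            [rng.uniform(margin, rows - margin), rng.uniform(margin, cols - margin)]
        )
        if all(np.sum((cand - c) ** 2) >= min_d2 for c in centers):
            centers.append(cand)
    return np.vstack(centers)


def _territories(
    shape: Tuple[int, int], centers: np.ndarray, radius: float
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nearest-centre territories clipped at ``radius``.

    Returns (labels, d1, gap) where d1 is the distance to the nearest centre
    and gap = d2 - d1 the bisector clearance (inf for a single cell).
    """
    rows, cols = shape
    labels = np.zeros(shape, dtype=np.int32)
    if len(centers) == 0:
        return labels, np.full(shape, np.inf), np.full(shape, np.inf)
    rr, cc = np.mgrid[0:rows, 0:cols]
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    tree = cKDTree(centers)
    k = min(2, len(centers))
    dist, idx = tree.query(pts, k=k)
    if k == 1:
        d1 = dist.reshape(shape)
        gap = np.full(shape, np.inf)
        nearest = idx.reshape(shape)
    else:
        d1 = dist[:, 0].reshape(shape)
        gap = (dist[:, 1] - dist[:, 0]).reshape(shape)
        nearest = idx[:, 0].reshape(shape)
    labels = np.where(d1 <= radius, nearest + 1, 0).astype(np.int32)
    return labels, d1, gap


def _elliptical_q2(
    rr: np.ndarray, cc: np.ndarray, center: np.ndarray, a: float, b: float, theta: float
) -> np.ndarray:
    dr = rr - center[0]
    dc = cc - center[1]
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2


def _add_gaussian_spot(
    canvas: np.ndarray, row: float, col: float, peak: float, sigma: float
) -> None:
    rows, cols = canvas.shape
    half = int(np.ceil(4 * sigma))
    r0, r1 = max(0, int(row) - half), min(rows, int(row) + half + 1)
    c0, c1 = max(0, int(col) - half), min(cols, int(col) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    canvas[r0:r1, c0:c1] += peak * np.exp(
        -((rr - row) ** 2 + (cc - col) ** 2) / (2.0 * sigma**2)
    )


def _sample_ld_positions(
    n_ld: int,
    candidates: np.ndarray,
    min_sep: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pick ``n_ld`` candidate pixels (with sub-pixel jitter) keeping a
    minimum pairwise separation; the separation constraint is halved and then
    dropped if the cell is too crowded to honour it."""
    if n_ld == 0:
        return np.zeros((0, 2))
    if len(candidates) == 0:
        raise PlacementError("no candidate pixels for droplet placement")
    for sep in (min_sep, min_sep / 2.0, 0.0):
        placed = np.empty((n_ld, 2))
        n_placed = 0
        tries = 0
        max_tries = 50 * n_ld + 200
        sep2 = sep * sep
        while n_placed < n_ld and tries < max_tries:
            tries += 1
            base = candidates[rng.integers(len(candidates))]
            pos = base + rng.uniform(-0.5, 0.5, size=2)
            if sep2 == 0 or n_placed == 0 or (
                ((placed[:n_placed] - pos) ** 2).sum(axis=1).min() >= sep2
            ):
                placed[n_placed] = pos
                n_placed += 1
        if n_placed == n_ld:
            return placed
    raise PlacementError(f"could not place {n_ld} droplets in cell territory")


def render_scene(
    params: SceneParams,
) -> Tuple[np.ndarray, np.ndarray, SceneTruth]:
    """Render one field; returns (nuclei_image, droplet_image, truth).

    Both images are uint16 of ``params.field_shape``. Identical parameters
    (including seed) produce bit-identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    shape = params.field_shape
    rows, cols = shape

    centers = _place_centers(params, rng)
    n = len(centers)

    # per-cell nucleus shape
    jit = params.nucleus_radius_jitter_px
    axes_a = np.maximum(params.nucleus_radius_px + rng.uniform(-jit, jit, n), 3.0)
    axes_b = np.maximum(params.nucleus_radius_px + rng.uniform(-jit, jit, n), 3.0)
    thetas = rng.uniform(0, np.pi, n)

    territory, _d1, gap = _territories(shape, centers, params.cytoplasm_radius_px)

    # nucleus label map + rendered nuclei channel
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    nuclei = np.zeros(shape, dtype=float)
    for i in range(n):
        a, b, th = axes_a[i], axes_b[i], thetas[i]
        half = int(np.ceil(max(a, b))) + 2
        r0 = max(0, int(centers[i, 0]) - half)
        r1 = min(rows, int(centers[i, 0]) + half + 1)
        c0 = max(0, int(centers[i, 1]) - half)
        c1 = min(cols, int(centers[i, 1]) + half + 1)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        q2 = _elliptical_q2(rr, cc, centers[i], a, b, th)
        inside = q2 <= 1.0
        nucleus_labels[r0:r1, c0:c1][inside] = i + 1
        nuclei[r0:r1, c0:c1] += np.where(
            inside, params.nucleus_peak_intensity * np.exp(-q2 / 2.0), 0.0
        )
    # a nucleus always belongs to its own cell territory, even where it pokes
    # past the nearest-centre boundary of a close neighbour
    nuc_mask = nucleus_labels > 0
    territory[nuc_mask] = nucleus_labels[nuc_mask]

    # droplet counts and positions
    counts = rng.poisson(params.ld_rate, n).astype(int) if n else np.zeros(0, int)
    margin = params.ld_margin_px
    dmin, dmax = params.ld_diameter_px
    droplets = np.zeros(shape, dtype=float)
    ld_rows: List[dict] = []
    if n:
        terr_flat = territory
        rr_all, cc_all = np.mgrid[0:rows, 0:cols]
        for i in range(n):
            n_ld = counts[i]
            if n_ld == 0:
                continue
            mask = terr_flat == i + 1
            # clearance from the territory bisector and from the nucleus edge
            mask = mask & (gap >= 2.0 * margin)
            q2 = _elliptical_q2(
                rr_all, cc_all, centers[i], axes_a[i] + margin, axes_b[i] + margin, thetas[i]
            )
            cand_mask = mask & (q2 > 1.0) & (nucleus_labels == 0)
            if not cand_mask.any():
                cand_mask = (terr_flat == i + 1) & (nucleus_labels == 0)
            candidates = np.column_stack(np.nonzero(cand_mask)).astype(float)
            positions = _sample_ld_positions(
                n_ld, candidates, params.ld_min_separation_px, rng
            )
            diams = rng.uniform(dmin, dmax, n_ld)
            peaks = params.ld_peak_intensity * rng.uniform(0.8, 1.2, n_ld)
            for j in range(n_ld):
                sigma = diams[j] / 2.355  # FWHM -> sigma
                _add_gaussian_spot(droplets, positions[j, 0], positions[j, 1], peaks[j], sigma)
                ld_rows.append(
                    {
                        "cell_id": i + 1,
                        "row": positions[j, 0],
                        "col": positions[j, 1],
                        "diameter_px": diams[j],
                        "peak": peaks[j],
                    }
                )

    # optics + camera
    def _finish(canvas: np.ndarray) -> np.ndarray:
        img = canvas + params.background_level
        if params.psf_sigma_px > 0:
            img = ndi.gaussian_filter(img, params.psf_sigma_px)
        if params.noise_sd > 0:
            img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
        return np.clip(np.round(img), 0, MAX_UINT16).astype(np.uint16)

    nuclei_img = _finish(nuclei)
    droplet_img = _finish(droplets)

    cells_df = pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1, dtype=int),
            "nuc_row": centers[:, 0] if n else np.zeros(0),
            "nuc_col": centers[:, 1] if n else np.zeros(0),
            "nuc_a": axes_a,
            "nuc_b": axes_b,
            "nuc_theta": thetas,
            "ld_count": counts,
        }
    )
    lds_df = pd.DataFrame(
        ld_rows, columns=["cell_id", "row", "col", "diameter_px", "peak"]
    )
    truth = SceneTruth(
        cells=cells_df,
        lds=lds_df,
        territory_labels=territory,
        nucleus_labels=nucleus_labels,
    )
    return nuclei_img, droplet_img, truth


# ---------------------------------------------------------------------------
# plates


def treatment_key(row: pd.Series) -> str:
    """Treatment label of a plate-map row: extract_id for extracts, else role."""
    role = row.get("role", "extract")
    if role == "extract":
        return str(row["extract_id"])
    return str(role)


@dataclass
class FieldData:
    """Rendered images + truth for one field of one well."""

    nuclei: np.ndarray
    droplets: np.ndarray
    truth: SceneTruth


def render_plate(
    spec: PlateSpec,
) -> Tuple[Dict[str, List[FieldData]], pd.DataFrame]:
    """Render every well of the plate.

    Returns (fields, well_truth): ``fields`` maps well_id to a list of
    :class:`FieldData` (one per field), ``well_truth`` has one row per well
    with the treatment, planted rate/survival, surviving cell count and true
    mean LDs/cell pooled over fields. Deterministic under ``spec.seed``.
    """
    spec.scenario.validate()
    layout = spec.layout.reset_index(drop=True)
    fields: Dict[str, List[FieldData]] = {}
    truth_rows = []
    for widx, lrow in layout.iterrows():
        well = str(lrow["well_id"])
        treatment = treatment_key(lrow)
        conc = lrow.get("concentration", None)
        conc = float(conc) if conc is not None and pd.notna(conc) else None
        lam = spec.scenario.ld_rate(treatment, conc)
        survival = spec.scenario.survival(treatment, conc)
        well_fields: List[FieldData] = []
        total_cells = 0
        total_lds = 0
        for f in range(spec.fields_per_well):
            ss = np.random.SeedSequence([int(spec.seed), int(widx), int(f)])
            state = ss.generate_state(2)
            thin_rng = np.random.default_rng(int(state[0]))
            n_cells = int(thin_rng.binomial(spec.base_params.n_cells, survival))
            scene_seed = int(state[1]) % (2**31)
            p = replace(
                spec.base_params, n_cells=n_cells, ld_rate=lam, seed=scene_seed
            )
            nuc, drp, truth = render_scene(p)
            well_fields.append(FieldData(nuc, drp, truth))
            total_cells += truth.n_cells
            total_lds += int(truth.cells["ld_count"].sum())
        fields[well] = well_fields
        truth_rows.append(
            {
                "well_id": well,
                "treatment": treatment,
                "extract_id": lrow.get("extract_id", ""),
                "role": lrow.get("role", "extract"),
                "concentration": conc,
                "ld_rate": lam,
                "survival": survival,
                "n_cells_true": total_cells,
                "true_total_lds": total_lds,
                "true_mean_lds_per_cell": (total_lds / total_cells)
                if total_cells
                else float("nan"),
            }
        )
    return fields, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# scenarios


def _controls() -> Dict[str, float]:
    return {
        "media-only": OLEIC_RATE,  # loaded, untreated
        "inactive-extract": OLEIC_RATE,
        "triacsin-C": 0.2 * OLEIC_RATE,  # 1 uM optimum strongly suppresses LDs
        "delipidated": DELIPIDATED_RATE,
        "oleic": OLEIC_RATE,
    }


#: scale of the LD rate along the triacsin-C dose ladder (uM -> scale)
TRIACSIN_LADDER: Dict[float, float] = {0.0: 1.0, 0.1: 0.8, 0.3: 0.5, 1.0: 0.2, 3.0: 0.05}

#: scale of the LD rate along a heterofibrin-like inhibitor ladder (uM -> scale);
#: 0.46 at 20 uM corresponds to ~60% inhibition against the loaded/delipidated window
INHIBITOR_LADDER: Dict[float, float] = {1.0: 0.97, 5.0: 0.85, 10.0: 0.65, 20.0: 0.46, 50.0: 0.30}


def scenario_library() -> Dict[str, ScenarioConfig]:
    """Named scenarios covering the assay regimes the simulator emulates."""
    lib: Dict[str, ScenarioConfig] = {}
    lib["delipidated-baseline"] = ScenarioConfig(
        name="delipidated-baseline", ld_rate_map=dict(_controls())
    )
    lib["oleic-loading"] = ScenarioConfig(
        name="oleic-loading", ld_rate_map=dict(_controls())
    )
    tri = dict(_controls())
    for conc, scale in TRIACSIN_LADDER.items():
        tri[f"triacsin-C:{format(conc, 'g')}"] = OLEIC_RATE * scale
    lib["triacsin-dose-series"] = ScenarioConfig(
        name="triacsin-dose-series", ld_rate_map=tri
    )
    inh = dict(_controls())
    for conc, scale in INHIBITOR_LADDER.items():
        inh[f"inhibitor:{format(conc, 'g')}"] = OLEIC_RATE * scale
    lib["inhibitor-dose-series"] = ScenarioConfig(
        name="inhibitor-dose-series", ld_rate_map=inh
    )
    tox = dict(_controls())
    tox["toxic-extract"] = OLEIC_RATE
    lib["cytotoxic-extract"] = ScenarioConfig(
        name="cytotoxic-extract",
        ld_rate_map=tox,
        toxicity_map={"toxic-extract": 0.3},
    )
    lib["uptake-timecourse"] = ScenarioConfig(
        name="uptake-timecourse",
        ld_rate_map=dict(_controls()),
        uptake=UptakeKinetics(),
    )
    lib["primary-screen"] = screen_plate_scenario()
    for cfg in lib.values():
        cfg.validate()
    return lib


def screen_plate_scenario(
    n_extracts: int = 42,
    ld_rate: float = OLEIC_RATE,
    survival: float = 0.95,
    increase_ids: Sequence[str] = ("EXT01",),
    decrease_ids: Sequence[str] = ("EXT02", "EXT03"),
    toxic_ids: Sequence[str] = ("EXT04", "EXT05"),
    increase_factor: float = 3.0,
    decrease_factor: float = 0.4,
    toxic_survival: float = 0.3,
) -> ScenarioConfig:
    """Primary-screen plate scenario with planted actives.

    Plain extracts sit at the oleic-loaded rate with mild plating variability
    (``survival``); planted increasers/decreasers scale the rate, planted
    cytotoxic extracts thin the surviving cells.
    """
    rates: Dict[str, float] = dict(_controls())
    tox: Dict[str, float] = {}
    for i in range(1, n_extracts + 1):
        eid = f"EXT{i:02d}"
        rates[eid] = ld_rate
        tox[eid] = survival
    for eid in increase_ids:
        rates[eid] = ld_rate * increase_factor
    for eid in decrease_ids:
        rates[eid] = ld_rate * decrease_factor
    for eid in toxic_ids:
        tox[eid] = toxic_survival
    cfg = ScenarioConfig(name="primary-screen", ld_rate_map=rates, toxicity_map=tox)
    cfg.validate()
    return cfg


def simulate_uptake_series(
    kinetics: UptakeKinetics,
    times: Sequence[float],
    noise_frac: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Integrated cytoplasmic-intensity time course with relative Gaussian noise."""
    t = np.asarray(times, dtype=float)
    y = kinetics.intensity(t)
    if noise_frac > 0:
        if rng is None:
            rng = np.random.default_rng()
        y = y + rng.normal(0.0, noise_frac * kinetics.i_max, size=t.shape)
    return y
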