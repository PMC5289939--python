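"""Synthetic monolayers, screens and rendered fields with ground truth.

Three levels of synthesis:

``generate_cells``
    Draws per-cell feature tables from a population specification. Features
    come from truncated normals tied together by a latent "crowding" factor,
    so that cell area and protrusiveness fall while neighbour fraction and
    local cell density rise in crowded cells — the sign structure observed
    in wild-type epithelial monolayers. The YAP log-ratio is the supplied
    linear model evaluated on the drawn features, plus an optional direct
    offset (delta) and Gaussian residual noise; nuclear and ring intensities
    are back-derived so that log10(nuc/ring) reproduces the ratio exactly.

``generate_screen``
    Assembles a multi-well screen: control wells seeded over a 4-fold
    density range with delta = 0, "indirect" perturbations that shift shape
    only, and "direct" perturbations that carry a nonzero delta. Ground
    truth is returned alongside for scoring tests.

``render_field``
    Rasterizes a cell layout into a 3-channel field image (DNA / actin /
    YAP) of piecewise-constant plateaus with optional blur and Poisson
    noise, together with ground-truth nucleus and cell label maps.

All randomness is seeded explicitly; identical specs give bit-identical
output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .config import MLR6_FEATURES, PIXEL_SIZE_UM, RING_BASE_INTENSITY
from .containers import FieldImage, LabelMaps
from .model import ShapeModelResults, reference_mlr6

__all__ = [
    "PopulationSpec",
    "TreatmentSpec",
    "PlateSpec",
    "ScreenSpec",
    "ScreenDataset",
    "CellPlacement",
    "FieldLayout",
    "generate_cells",
    "generate_screen",
    "render_field",
    "layout_monolayer",
    "default_generative_model",
]

#: Reference seeding density (cells per well) at which feature means are
#: specified; density-coupling maps rescale means relative to this.
REFERENCE_DENSITY: float = 500.0

#: Power-law exponents of the default density-coupling maps:
#: mean_f(d) = base_mean_f * (d / REFERENCE_DENSITY) ** exponent_f.
#: Signs follow the observed density trends: crowding shrinks cells and
#: protrusions and raises contact and local density.
DENSITY_COUPLING_EXPONENTS: dict[str, float] = {
    "cellA": -0.5,
    "nucA": -0.1,
    "NF": 0.5,
    "LCD": 1.0,
    "proA": -0.3,
    "proX": -0.3,
}

#: Loadings of the per-cell latent crowding factor; they set the signs (and
#: roughly the magnitudes) of the pairwise feature correlations.
FEATURE_LATENT_LOADINGS: dict[str, float] = {
    "cellA": -0.6,
    "nucA": -0.2,
    "NF": 0.6,
    "LCD": 0.7,
    "proA": -0.4,
    "proX": -0.5,
}

#: Valid ranges for truncation, per feature.
FEATURE_BOUNDS: dict[str, tuple[float, float]] = {
    "cellA": (100.0, np.inf),
    "nucA": (25.0, np.inf),
    "NF": (0.0, 1.0),
    "LCD": (1e-3, np.inf),
    "proA": (0.0, np.inf),
    "proX": (0.0, 1.0),
}

_DEFAULT_MEANS = {
    "cellA": 3000.0,
    "nucA": 500.0,
    "NF": 0.35,
    "LCD": 30.0,
    "proA": 250.0,
    "proX": 0.18,
}
_DEFAULT_DISPERSIONS = {
    "cellA": 700.0,
    "nucA": 90.0,
    "NF": 0.18,
    "LCD": 9.0,
    "proA": 140.0,
    "proX": 0.10,
}


def default_generative_model() -> ShapeModelResults:
    """Linear model used to simulate realistic YAP ratios in screens.

    Coefficients are sized to the package's default feature scales so that
    wild-type ratios land around 0.1-0.3 log10 units with the published
    residual scale (SD 0.1054); signs match the wild-type correlation
    structure (area and protrusion up, contact and crowding down).
    """
    return ShapeModelResults(
        coefficients={
            "cellA": 3.242e-5,
            "nucA": -2.0e-4,
            "NF": -0.1413,
            "LCD": -3.3e-3,
            "proA": 3.86e-5,
            "proX": -0.1357,
        },
        intercept=0.32,
        standardized_betas={},
        r_squared=float("nan"),
        rmse=0.1054,
        n_train=0,
        feature_order=MLR6_FEATURES,
        plate_id="synthetic-generative",
    )


# --------------------------------------------------------------------------
# population-level generation
# --------------------------------------------------------------------------


@dataclass
class PopulationSpec:
    """Statistical description of one well's cell population."""

    seeding_density: float = REFERENCE_DENSITY
    feature_means: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    feature_dispersions: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DISPERSIONS)
    )
    density_coupling: dict[str, float] = field(
        default_factory=lambda: dict(DENSITY_COUPLING_EXPONENTS)
    )
    direct_effect_delta: float = 0.0
    noise_sd: float = 0.1054
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.seeding_density > 0:
            raise ValueError(f"seeding_density must be > 0, got {self.seeding_density}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for f in MLR6_FEATURES:
            if f not in self.feature_means:
                raise ValueError(f"feature_means missing entry for {f!r}")
            if f not in self.feature_dispersions:
                raise ValueError(f"feature_dispersions missing entry for {f!r}")
            if self.feature_dispersions[f] < 0:
                raise ValueError(
                    f"feature_dispersions[{f!r}] must be >= 0, got "
                    f"{self.feature_dispersions[f]}"
                )
        # unit-interval features keep their means in range
        for f in ("NF", "proX"):
            self.feature_means[f] = float(np.clip(self.feature_means[f], 0.0, 1.0))

    def coupled_means(self) -> dict[str, float]:
        """Feature means after applying the density-coupling power laws."""
        rel = self.seeding_density / REFERENCE_DENSITY
        out = {}
        for f in MLR6_FEATURES:
            m = self.feature_means[f] * rel ** self.density_coupling.get(f, 0.0)
            lo, hi = FEATURE_BOUNDS[f]
            out[f] = float(np.clip(m, lo, min(hi, 1.0) if hi == 1.0 else hi))
        return out

    def with_(self, **kwargs) -> "PopulationSpec":
        """Return a copy with fields replaced (means/dispersions copied)."""
        new = replace(
            self,
            feature_means=dict(self.feature_means),
            feature_dispersions=dict(self.feature_dispersions),
            density_coupling=dict(self.density_coupling),
        )
        for k, v in kwargs.items():
            if k == "feature_means":
                new.feature_means.update(v)
            elif k == "feature_dispersions":
                new.feature_dispersions.update(v)
            else:
                setattr(new, k, v)
        new.validate()
        return new

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PopulationSpec":
        return cls(**json.loads(text))


def generate_cells(
    spec: PopulationSpec,
    n: int,
    model: ShapeModelResults | None = None,
    well_id: str = "well",
    field_id: str = "f01",
    plate_id: str = "plate1",
) -> pd.DataFrame:
    """Draw ``n`` cell records from ``spec`` under the linear model.

    Returns a feature table with one row per cell. ``yap_ratio`` equals the
    model's linear predictor on the drawn features plus
    ``spec.direct_effect_delta`` and Gaussian noise of SD ``spec.noise_sd``;
    ``yap_nuc_mean``/``yap_ring_mean`` are back-derived so that
    log10(nuc/ring) equals ``yap_ratio`` exactly (ring mean fixed at the
    configured base intensity).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    spec.validate()
    if model is None:
        model = default_generative_model()
    rng = np.random.default_rng(spec.seed)
    means = spec.coupled_means()
    z = rng.standard_normal(n)  # latent crowding factor

    feats: dict[str, np.ndarray] = {}
    for f in MLR6_FEATURES:
        load = FEATURE_LATENT_LOADINGS.get(f, 0.0)
        disp = spec.feature_dispersions[f]
        resid_scale = np.sqrt(max(0.0, 1.0 - load**2))
        x = means[f] + disp * (load * z + resid_scale * rng.standard_normal(n))
        lo, hi = FEATURE_BOUNDS[f]
        # redraw the idiosyncratic part for out-of-range cells, then clip
        for _ in range(20):
            bad = (x < lo) | (x > hi)
            if not bad.any():
                break
            x[bad] = means[f] + disp * (
                load * z[bad] + resid_scale * rng.standard_normal(int(bad.sum()))
            )
        feats[f] = np.clip(x, lo, hi)

    table = pd.DataFrame(feats)
    lin = model.linear_predictor(table)
    noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else 0.0
    yap_ratio = lin + spec.direct_effect_delta + noise

    ring_mean = np.full(n, RING_BASE_INTENSITY)
    nuc_mean = ring_mean * 10.0**yap_ratio
    table["anuc_over_acell"] = table["nucA"] / table["cellA"]
    table["yap_nuc_mean"] = nuc_mean
    table["yap_ring_mean"] = ring_mean
    table["yap_ratio"] = yap_ratio
    table["yap_total"] = nuc_mean * table["nucA"] + ring_mean * (
        table["cellA"] - table["nucA"]
    )
    table.insert(0, "cell_id", [f"{well_id}:{field_id}:{i}" for i in range(n)])
    table.insert(1, "well_id", well_id)
    table.insert(2, "field_id", field_id)
    table.insert(3, "plate_id", plate_id)
    table["qc_flags"] = ""
    return table


# --------------------------------------------------------------------------
# screen-level generation
# --------------------------------------------------------------------------


@dataclass
class TreatmentSpec:
    """One screened target: name, replicate wells and its population."""

    target: str
    n_replicates: int
    population: PopulationSpec
    kind: str = "indirect"  # "direct" | "indirect" (annotation only)


@dataclass
class PlateSpec:
    plate_id: str
    control_densities: Sequence[float]
    treatments: list[TreatmentSpec] = field(default_factory=list)

    def validate(self) -> None:
        if len(self.control_densities) < 12:
            raise ValueError(
                f"plate {self.plate_id}: needs >= 12 control wells, "
                f"got {len(self.control_densities)}"
            )
        dens = np.asarray(self.control_densities, dtype=float)
        if np.any(dens <= 0):
            raise ValueError(f"plate {self.plate_id}: control densities must be > 0")
        if dens.max() / dens.min() < 4.0:
            raise ValueError(
                f"plate {self.plate_id}: control densities must span a >= 4-fold "
                f"range (got {dens.max() / dens.min():.2f})"
            )


@dataclass
class ScreenSpec:
    plates: list[PlateSpec]
    replicate_rule: str = "2of2"  # "2of2" | "3of4"
    control_population: PopulationSpec = field(default_factory=PopulationSpec)
    seed: int = 0

    def validate(self) -> None:
        if self.replicate_rule not in ("2of2", "3of4"):
            raise ValueError(f"unknown replicate_rule {self.replicate_rule!r}")
        required = {"2of2": 2, "3of4": 4}[self.replicate_rule]
        for plate in self.plates:
            plate.validate()
            for t in plate.treatments:
                if t.n_replicates != required:
                    raise ValueError(
                        f"target {t.target!r}: replicate_rule {self.replicate_rule} "
                        f"requires {required} replicates, got {t.n_replicates}"
                    )


@dataclass
class ScreenDataset:
    """A simulated screen: per-cell table, layout, and ground truth."""

    cells: pd.DataFrame
    layout: pd.DataFrame
    ground_truth: pd.DataFrame
    replicate_rule: str


_ROWS = "ABCDEFGHIJKLMNOP"


def _well_name(i: int) -> str:
    # distribute sequential wells over a 384-well grid, stepping rows and
    # columns so that consecutive wells never share a row or a column
    row = i % 16
    col = (i * 5 + i // 16) % 24
    return f"{_ROWS[row]}{col + 1}"


def generate_screen(
    spec: ScreenSpec, model: ShapeModelResults | None = None
) -> ScreenDataset:
    """Simulate every well of ``spec`` under the generative linear model."""
    spec.validate()
    if model is None:
        model = default_generative_model()
    cells_parts, layout_rows, truth_rows = [], [], []
    for p_idx, plate in enumerate(spec.plates):
        widx = 0
        for d_idx, density in enumerate(plate.control_densities):
            well = _well_name(widx)
            widx += 1
            seed = int(np.random.default_rng([spec.seed, p_idx, widx]).integers(2**31))
            pop = spec.control_population.with_(
                seeding_density=float(density), direct_effect_delta=0.0, seed=seed
            )
            tbl = generate_cells(
                pop, int(round(density)), model, well_id=well, plate_id=plate.plate_id
            )
            cells_parts.append(tbl)
            layout_rows.append(
                dict(
                    plate=plate.plate_id, well=well, treatment="mock", replicate=d_idx,
                    is_control=True, seeded_cells=int(round(density)), true_delta=0.0,
                )
            )
        for t in plate.treatments:
            for r in range(t.n_replicates):
                well = _well_name(widx)
                widx += 1
                seed = int(
                    np.random.default_rng([spec.seed, p_idx, widx]).integers(2**31)
                )
                pop = t.population.with_(seed=seed)
                n = int(round(pop.seeding_density))
                tbl = generate_cells(
                    pop, n, model, well_id=well, plate_id=plate.plate_id
                )
                cells_parts.append(tbl)
                layout_rows.append(
                    dict(
                        plate=plate.plate_id, well=well, treatment=t.target,
                        replicate=r, is_control=False, seeded_cells=n,
                        true_delta=t.population.direct_effect_delta,
                    )
                )
            truth_rows.append(
                dict(
                    target=t.target, kind=t.kind,
                    true_delta=t.population.direct_effect_delta,
                    feature_means=json.dumps(t.population.feature_means),
                )
            )
    return ScreenDataset(
        cells=pd.concat(cells_parts, ignore_index=True),
        layout=pd.DataFrame(layout_rows),
        ground_truth=pd.DataFrame(
            truth_rows, columns=["target", "kind", "true_delta", "feature_means"]
        ),
        replicate_rule=spec.replicate_rule,
    )


# --------------------------------------------------------------------------
# field rendering
# --------------------------------------------------------------------------


@dataclass
class CellPlacement:
    """Geometry and target intensity ratio of one rendered cell.

    ``center`` is (row, col); the cell territory is the set of pixels whose
    nearest placement center is this cell and whose distance to it is at
    most ``cell_radius`` — neighbouring territories therefore abut along
    Voronoi boundaries when radii overlap. The nucleus is an axis-aligned
    ellipse of semi-axes ``nucleus_radii``. ``appendage_rects`` are
    rectangles (r0, r1, c0, c1) rendered as dim protrusive cytoplasm at
    ``appendage_frac`` of the cytoplasm plateau.
    """

    center: tuple[float, float]
    cell_radius: float = 40.0
    nucleus_radii: tuple[float, float] = (12.0, 12.0)
    target_ratio: float = 0.2  # log10 nuclear/ring
    appendage_rects: list[tuple[int, int, int, int]] = field(default_factory=list)
    appendage_frac: float = 0.5


@dataclass
class FieldLayout:
    shape: tuple[int, int]
    placements: list[CellPlacement]
    blur_sigma: float = 0.0
    poisson_noise: bool = False
    seed: int = 0
    background: float = 20.0


def layout_monolayer(
    n_cells: int,
    shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    target_ratio: float = 0.2,
    jitter_frac: float = 0.25,
) -> FieldLayout:
    """Place ~n_cells on a jittered grid so neighbouring territories touch."""
    rng = np.random.default_rng(seed)
    H, W = shape
    ncol = int(np.ceil(np.sqrt(n_cells * W / H)))
    nrow = int(np.ceil(n_cells / ncol))
    sr, sc = H / nrow, W / ncol
    placements = []
    for i in range(nrow):
        for j in range(ncol):
            if len(placements) >= n_cells:
                break
            r = (i + 0.5) * sr + rng.uniform(-jitter_frac, jitter_frac) * sr
            c = (j + 0.5) * sc + rng.uniform(-jitter_frac, jitter_frac) * sc
            placements.append(
                CellPlacement(
                    center=(float(np.clip(r, 4, H - 5)), float(np.clip(c, 4, W - 5))),
                    cell_radius=0.75 * max(sr, sc),
                    nucleus_radii=(0.18 * sr, 0.18 * sc),
                    target_ratio=target_ratio,
                )
            )
    return FieldLayout(shape=shape, placements=placements, seed=seed)


def render_field(
    layout: FieldLayout,
    pixel_size_um: float | None = None,
    well_id: str = "well",
    field_id: str = "f01",
) -> tuple[FieldImage, LabelMaps]:
    """Rasterize a layout into a 3-channel field plus ground-truth labels.

    The YAP channel is a piecewise-constant plateau image: within each cell
    the nucleus plateau is ``ring_base * 10**target_ratio`` and the
    cytoplasm plateau is the ring base intensity, so the true mean
    nuclear/ring log-ratio on the ground-truth masks equals
    ``target_ratio`` exactly when blur and noise are off.
    """
    H, W = layout.shape
    n = len(layout.placements)
    if n == 0:
        raise ValueError("layout has no placements")
    # crude capacity check: total nominal cell area must fit the frame
    area = sum(np.pi * p.cell_radius**2 for p in layout.placements)
    if area > 4.0 * H * W:
        raise ValueError(
            f"field {H}x{W} too small for {n} cells of the requested radii"
        )
    for p in layout.placements:
        r, c = p.center
        if not (0 <= r < H and 0 <= c < W):
            raise ValueError(f"placement center {p.center} outside the {H}x{W} field")

    rr, cc = np.mgrid[0:H, 0:W]
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    centers = np.array([p.center for p in layout.placements])
    tree = cKDTree(centers)
    dist, idx = tree.query(pts)
    radii = np.array([p.cell_radius for p in layout.placements])
    cells = np.where(dist <= radii[idx], idx + 1, 0).reshape(H, W).astype(np.int32)

    nuclei = np.zeros((H, W), dtype=np.int32)
    for k, p in enumerate(layout.placements, start=1):
        r0, c0 = p.center
        ra, rb = p.nucleus_radii
        mask = ((rr - r0) / ra) ** 2 + ((cc - c0) / rb) ** 2 <= 1.0
        nuclei[mask & (cells == k)] = k

    # appendages extend their cell's territory
    for k, p in enumerate(layout.placements, start=1):
        for r0, r1, c0, c1 in p.appendage_rects:
            sl = (slice(max(r0, 0), min(r1, H)), slice(max(c0, 0), min(c1, W)))
            patch = cells[sl]
            patch[patch == 0] = k

    bg = layout.background
    dna = np.full((H, W), bg)
    dna[nuclei > 0] = 3000.0
    actin = np.full((H, W), bg)
    actin[cells > 0] = 800.0
    # edge enhancement: bright rim along each cell territory border
    interior = ndi.grey_erosion(cells, size=3) == ndi.grey_dilation(cells, size=3)
    border = (cells > 0) & ~interior
    actin[border] = 2000.0

    yap = np.full((H, W), bg)
    for k, p in enumerate(layout.placements, start=1):
        cyto = (cells == k) & (nuclei == 0)
        yap[cyto] = RING_BASE_INTENSITY
        yap[nuclei == k] = RING_BASE_INTENSITY * 10.0**p.target_ratio
        for r0, r1, c0, c1 in p.appendage_rects:
            sl = (slice(max(r0, 0), min(r1, H)), slice(max(c0, 0), min(c1, W)))
            sub = (cells[sl] == k) & (nuclei[sl] == 0)
            yap[sl][sub] = p.appendage_frac * RING_BASE_INTENSITY

    if layout.blur_sigma > 0:
        dna = ndi.gaussian_filter(dna, layout.blur_sigma)
        actin = ndi.gaussian_filter(actin, layout.blur_sigma)
        yap = ndi.gaussian_filter(yap, layout.blur_sigma)
    if layout.poisson_noise:
        rng = np.random.default_rng(layout.seed)
        dna = rng.poisson(dna).astype(float)
        actin = rng.poisson(actin).astype(float)
        yap = rng.poisson(yap).astype(float)

    img = FieldImage(
        dna=dna, actin=actin, yap=yap,
        pixel_size_um=PIXEL_SIZE_UM if pixel_size_um is None else pixel_size_um,
        well_id=well_id, field_id=field_id,
    )
    return img, LabelMaps(nuclei=nuclei, cells=cells)
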