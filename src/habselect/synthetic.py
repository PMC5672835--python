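"""Synthetic landscapes and telemetry with known selection coefficients.

Every downstream stage (selection ratios, K-select, thinning, suitability)
needs inputs with a known truth.  This module builds a patchy categorical
land-cover raster plus continuous eco-geographical layers (elevation, slope,
an NDVI-like greenness index and Euclidean-distance layers from a synthetic
river and water points), then simulates radio-telemetry for a small set of
animals under an exponential (log-linear) resource-selection function: inside
each animal's circular home-range disc, used resource units are drawn with
probability proportional to exp(sum_v beta_v z_v) over globally standardized
EGVs z.  beta = 0 reproduces proportional (random) use; a large beta on one
cover-class proportion concentrates use in that class, giving the selection
and marginality estimators an analytically known target direction.

Randomness: one root seed; the landscape uses the child sequence
``SeedSequence([seed, 0])`` and animal k uses ``SeedSequence([seed, 1000+k])``,
so a single animal can be regenerated without disturbing the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .resource_units import RasterGrid, RUStack, aggregate_to_ru, distance_layer
from .kselect import standardize

FINE_CELL = 30.0     # m, base raster resolution
RU_FACTOR = 3        # 30 m -> 90 m resource units


@dataclass
class SyntheticConfig:
    seed: int = 0
    grid_rows: int = 90
    grid_cols: int = 90
    n_cover_classes: int = 4
    patch_smoothing: float = 4.0       # sigma of the patch noise, in cells
    n_animals: int = 9
    points_per_animal_per_period: int = 200
    selection_coefficients: np.ndarray | None = None   # settled-period beta
    exploratory_coefficients: np.ndarray | None = None # defaults to beta
    home_range_centres: np.ndarray | None = None       # metres
    home_range_radii: np.ndarray | None = None         # metres
    period_mix: float = 0.5            # fraction of points labelled exploratory
    cell_size: float = FINE_CELL

    def __post_init__(self) -> None:
        if self.grid_rows < 30 or self.grid_cols < 30:
            raise ValueError("grid must be at least 30 x 30 cells")
        if self.n_cover_classes < 2:
            raise ValueError("need at least 2 cover classes")
        if self.patch_smoothing <= 0:
            raise ValueError("patch_smoothing must be positive")
        if self.n_animals < 1:
            raise ValueError("need at least 1 animal")
        if not (0 <= self.period_mix <= 1):
            raise ValueError("period_mix must be in [0, 1]")
        extent_x = self.grid_cols * self.cell_size
        extent_y = self.grid_rows * self.cell_size
        if self.home_range_centres is None:
            # default: centres on a ring around the landscape midpoint
            rng = np.random.default_rng(np.random.SeedSequence([self.seed, 77]))
            margin = 0.3
            cx = rng.uniform(margin * extent_x, (1 - margin) * extent_x,
                             self.n_animals)
            cy = rng.uniform(margin * extent_y, (1 - margin) * extent_y,
                             self.n_animals)
            self.home_range_centres = np.column_stack([cx, cy])
        self.home_range_centres = np.asarray(self.home_range_centres, float)
        if self.home_range_radii is None:
            self.home_range_radii = np.full(
                self.n_animals, 0.25 * min(extent_x, extent_y)
            )
        self.home_range_radii = np.asarray(self.home_range_radii, float)
        if (self.home_range_radii <= 0).any():
            raise ValueError("home-range radii must be positive")
        for (cx, cy), rad in zip(self.home_range_centres,
                                 self.home_range_radii):
            if (cx - rad < 0 or cx + rad > extent_x
                    or cy - rad < 0 or cy + rad > extent_y):
                raise ValueError(
                    "home-range disc extends outside the landscape"
                )

    def egv_names(self) -> list[str]:
        """Canonical EGV column order matching the beta matrix columns."""
        return (
            [f"prop_{c}" for c in range(self.n_cover_classes)]
            + ["elevation", "slope", "ndvi", "dist_river", "dist_water"]
        )

    @property
    def n_egvs(self) -> int:
        return self.n_cover_classes + 5


@dataclass
class SyntheticTruth:
    beta_settled: np.ndarray          # animal x EGV
    beta_exploratory: np.ndarray
    egv_names: list[str]
    centres: np.ndarray
    radii: np.ndarray
    point_ru: pd.DataFrame            # animal_id, period, ru_id per point
    seed: int = 0


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma,
                                mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_landscape(
    config: SyntheticConfig, max_attempts: int = 5
) -> tuple[RasterGrid, dict[str, RasterGrid]]:
    """Generate the categorical cover raster and continuous EGV layers.

    Cover classes come from smoothed Gaussian noise fields (argmax over
    classes), giving contiguous patches whose size scales with
    ``patch_smoothing``.  A degenerate draw in which one class covers every
    cell is regenerated (fresh child seed); persistent degeneracy raises.
    """
    shape = (config.grid_rows, config.grid_cols)
    origin = (0.0, config.grid_rows * config.cell_size)
    geom = dict(cell_size=config.cell_size, origin=origin)

    cover_vals = None
    for attempt in range(max_attempts):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 0, attempt])
        )
        fields = np.stack([
            _smooth_field(rng, shape, config.patch_smoothing)
            for _ in range(config.n_cover_classes)
        ])
        cand = np.argmax(fields, axis=0)
        if np.unique(cand).size >= 2:
            cover_vals = cand
            break
    if cover_vals is None:
        raise ValueError(
            "degenerate landscape: a single cover class fills the grid "
            "(patch_smoothing too large for this grid size)"
        )
    cover = RasterGrid(cover_vals.astype(float), **geom)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    elev_field = _smooth_field(rng, shape, 2.0 * config.patch_smoothing)
    elevation = 350.0 + 80.0 * elev_field  # m a.s.l., Vindhyan-plateau range

    gy, gx = np.gradient(elevation, config.cell_size)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))

    ndvi = 0.5 + 0.25 * _smooth_field(rng, shape, config.patch_smoothing)
    ndvi = np.clip(ndvi, -1.0, 1.0)

    # river: a meandering west-east polyline of cells
    river = np.zeros(shape, dtype=float)
    r = rng.integers(shape[0] // 4, 3 * shape[0] // 4)
    for c in range(shape[1]):
        river[r, c] = 1.0
        r = int(np.clip(r + rng.integers(-1, 2), 0, shape[0] - 1))
    dist_river = distance_layer(RasterGrid(river, **geom))

    # scattered water points
    water = np.zeros(shape, dtype=float)
    k = max(3, (shape[0] * shape[1]) // 2000)
    wr = rng.integers(0, shape[0], k)
    wc = rng.integers(0, shape[1], k)
    water[wr, wc] = 1.0
    dist_water = distance_layer(RasterGrid(water, **geom))

    continuous = {
        "elevation": RasterGrid(elevation, **geom),
        "slope": RasterGrid(slope, **geom),
        "ndvi": RasterGrid(ndvi, **geom),
        "dist_river": dist_river,
        "dist_water": dist_water,
    }
    return cover, continuous


def build_ru_stack(
    config: SyntheticConfig,
    cover: RasterGrid,
    continuous: dict[str, RasterGrid],
) -> RUStack:
    """Aggregate the fine landscape to resource units (90 m by default)."""
    stack = aggregate_to_ru(cover, continuous, factor=RU_FACTOR)
    # classes absent from the landscape still get a zero proportion column so
    # that the beta matrix columns always line up with egv_names()
    for c in range(config.n_cover_classes):
        col = f"prop_{c}"
        if col not in stack.table.columns:
            stack.table[col] = 0.0
    return stack


def generate_telemetry(
    config: SyntheticConfig,
    stack: RUStack,
    egv_order: list[str] | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate telemetry under the exponential RSF inside each disc.

    ``egv_order`` names the EGV column that each beta column refers to
    (default: ``config.egv_names()``); permuting it together with the beta
    columns leaves the simulated points identical (the linear predictor is
    evaluated in a canonical order).  Returns a telemetry table
    (animal_id, period, x, y, timestamp, sex) and the ground truth.
    """
    names = list(egv_order) if egv_order is not None else config.egv_names()
    if sorted(names) != sorted(config.egv_names()):
        raise ValueError("egv_order must be a permutation of the EGV names")
    beta_s = config.selection_coefficients
    if beta_s is None:
        beta_s = np.zeros((config.n_animals, config.n_egvs))
    beta_s = np.asarray(beta_s, dtype=float)
    if beta_s.shape != (config.n_animals, config.n_egvs):
        raise ValueError(
            f"selection_coefficients must be {config.n_animals} x "
            f"{config.n_egvs} (animals x EGVs {names})"
        )
    beta_e = config.exploratory_coefficients
    beta_e = beta_s if beta_e is None else np.asarray(beta_e, dtype=float)

    table = stack.table
    ztab, _ = standardize(table, columns=names)
    # canonical (sorted) evaluation order: the linear predictor is then
    # bit-identical under any consistent permutation of EGVs and beta
    sorted_idx = np.argsort(names)
    Z = ztab[np.array(names)[sorted_idx]].to_numpy()

    xy = table[["x", "y"]].to_numpy()
    ru_cell = RU_FACTOR * config.cell_size
    n_total = 2 * config.points_per_animal_per_period
    n_expl = int(round(config.period_mix * n_total))
    n_sett = n_total - n_expl

    records = []
    truth_rows = []
    for k in range(config.n_animals):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 1000 + k])
        )
        centre = config.home_range_centres[k]
        radius = config.home_range_radii[k]
        in_disc = np.nonzero(
            np.hypot(xy[:, 0] - centre[0], xy[:, 1] - centre[1]) <= radius
        )[0]
        if in_disc.size < 10:
            raise ValueError(
                f"animal {k}: home-range disc contains only {in_disc.size} "
                "RUs (< 10)"
            )
        animal = f"T{k + 1}"
        sex = "M" if k % 2 == 0 else "F"
        t0 = k * 100_000
        for period, beta, n_pts in (
            ("exploratory", beta_e[k], n_expl),
            ("settled", beta_s[k], n_sett),
        ):
            if n_pts == 0:
                continue
            eta = Z[in_disc] @ beta[sorted_idx]
            eta -= eta.max()
            prob = np.exp(eta)
            prob /= prob.sum()
            chosen = rng.choice(in_disc, size=n_pts, replace=True, p=prob)
            # uniform placement inside the chosen RU cell
            ux = rng.uniform(-0.5, 0.5, n_pts) * ru_cell
            uy = rng.uniform(-0.5, 0.5, n_pts) * ru_cell
            px = xy[chosen, 0] + ux
            py = xy[chosen, 1] + uy
            for i in range(n_pts):
                records.append(
                    dict(animal_id=animal, period=period,
                         x=px[i], y=py[i], timestamp=t0 + i, sex=sex)
                )
                truth_rows.append(
                    dict(animal_id=animal, period=period,
                         ru_id=int(table["ru_id"].iloc[chosen[i]]))
                )
            t0 += n_pts

    telemetry = pd.DataFrame(records)
    truth = SyntheticTruth(
        beta_settled=beta_s,
        beta_exploratory=beta_e,
        egv_names=names,
        centres=config.home_range_centres,
        radii=config.home_range_radii,
        point_ru=pd.DataFrame(truth_rows),
        seed=config.seed,
    )
    return telemetry, truth


def simulate(config: SyntheticConfig):
    """Full simulation: landscape, RU stack, telemetry, truth."""
    cover, continuous = generate_landscape(config)
    stack = build_ru_stack(config, cover, continuous)
    telemetry, truth = generate_telemetry(config, stack)
    return cover, continuous, stack, telemetry, truth
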