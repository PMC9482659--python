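"""Synthetic world generation with known ground truth.

This module stands in for the real-data inputs of an endemic-species climate
impact study: gridded bioclimatic layers (WorldClim-like), a partition of the
world into countries and nested ecoregions (megadiverse-country / ecoregion
masks), virtual endemic species with known Gaussian climatic niches, and
occurrence records sampled from each species' true range. Because the truth
(niche parameters, true suitability, true range) is known, the downstream
modelling pipeline can be validated as a recovery experiment — something the
real study, fitted to empirical occurrences, cannot do.

Climate layers are correlated, spatially autocorrelated random fields built
by mixing per-layer noise with shared latent fields (one latent per variable
family, temperature and precipitation) and low-pass filtering. Future
scenarios add per-layer drifts that accumulate across horizons; the "melting"
family is constructed — and verified at generation time — to be strictly more
dissimilar from the baseline than the "control" family, mirroring the
contrast between a freshwater-forced warming scenario and plain RCP 8.5.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import GridSpec

# The 19 bioclim-style layer names. Indices mirror the WorldClim convention:
# bio01 annual mean temperature, bio04 temperature seasonality, bio05 max
# temperature of warmest month, bio12 annual precipitation, bio14
# precipitation of driest month, bio15 precipitation seasonality, etc.
BIOCLIM_LAYERS: tuple[str, ...] = tuple(f"bio{i:02d}" for i in range(1, 20))

# Temperature-family layers share one latent field, precipitation-family
# layers another; this reproduces the block-correlation structure of real
# bioclim data (temperature variables strongly inter-correlated, likewise
# precipitation, weak correlation across families).
TEMPERATURE_LAYERS = BIOCLIM_LAYERS[:11]
PRECIPITATION_LAYERS = BIOCLIM_LAYERS[11:]

# Affine (offset, scale) per layer, mapping the standardized random field to
# plausible units (degC for temperature-like layers, mm for precipitation).
_LAYER_UNITS: dict[str, tuple[float, float]] = {
    **{name: (20.0 + 2.0 * i, 6.0) for i, name in enumerate(TEMPERATURE_LAYERS)},
    **{name: (900.0 - 60.0 * i, 250.0) for i, name in enumerate(PRECIPITATION_LAYERS)},
}
_LAYER_UNITS["bio04"] = (650.0, 180.0)   # seasonality: sd of monthly temps x100
_LAYER_UNITS["bio15"] = (60.0, 25.0)     # precip seasonality: CV in percent

BASELINE = "baseline"
CONTROL = "control"
MELTING = "melting"
HORIZONS = ("T1", "T2", "T3")


def subseed(seed: int, *tokens) -> int:
    """Stable sub-seed: hash of (seed, tokens), below 2**31.

    Used everywhere a top-level seed fans out to per-layer, per-species or
    per-replicate streams, so that adding one species never perturbs another.
    """
    key = ":".join(str(t) for t in (seed, *tokens))
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


@dataclass
class ClimateStack:
    """Named multi-layer climate grid for one scenario/horizon."""

    grid: GridSpec
    layers: dict[str, np.ndarray]
    scenario_id: str = BASELINE
    horizon: str = "T0"

    def __post_init__(self) -> None:
        names = list(self.layers)
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        for name, arr in self.layers.items():
            if arr.shape != self.grid.shape:
                raise ValueError(f"layer {name} shape {arr.shape} != grid {self.grid.shape}")

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def matrix(self, cells: np.ndarray, layer_names: list[str] | None = None) -> np.ndarray:
        """Raw layer values at flat cell indices, one column per layer."""
        names = layer_names if layer_names is not None else self.layer_names
        rows, cols = self.grid.unravel(np.asarray(cells))
        return np.column_stack([self.layers[n][rows, cols] for n in names])

    def standardized(self, stats: dict[str, tuple[float, float]] | None = None) -> "ClimateStack":
        """Z-scored copy; `stats` maps layer -> (mean, sd) to standardize against."""
        if stats is None:
            stats = self.layer_stats()
        layers = {
            name: (arr - stats[name][0]) / stats[name][1] for name, arr in self.layers.items()
        }
        return ClimateStack(self.grid, layers, self.scenario_id, self.horizon)

    def layer_stats(self) -> dict[str, tuple[float, float]]:
        """Per-layer (mean, sd) over all cells; sd floored to avoid 0-division."""
        return {
            name: (float(arr.mean()), max(float(arr.std()), 1e-12))
            for name, arr in self.layers.items()
        }


@dataclass
class WorldMask:
    """Country and ecoregion partition of the grid.

    ``country_id`` is 0 for ocean/none and 1..country_count otherwise; every
    ecoregion id occurs within exactly one country (nesting invariant).
    """

    grid: GridSpec
    country_id: np.ndarray
    ecoregion_id: np.ndarray
    country_count: int

    def country_cells(self, country: int) -> np.ndarray:
        """Sorted flat indices of the cells of one country."""
        return np.flatnonzero(self.country_id.ravel() == country)

    @property
    def land(self) -> np.ndarray:
        return self.country_id > 0


@dataclass
class VirtualSpecies:
    """A simulated endemic species with a known Gaussian niche.

    True suitability at a cell is exp(-sum_v (z_v - mu_v)^2 / (2 sigma_v^2))
    over the species' niche variables, with z_v the baseline-standardized
    layer value; the true range is the set of within-country cells whose
    suitability reaches the occupancy threshold tau.
    """

    species_id: str
    country_id: int
    niche_vars: list[str]
    mu: dict[str, float]
    sigma: dict[str, float]
    tau: float
    layer_stats: dict[str, tuple[float, float]]
    true_suitability: np.ndarray = field(repr=False)
    true_range: np.ndarray = field(repr=False)

    def suitability_from_params(self, stack: ClimateStack) -> np.ndarray:
        """Recompute suitability from stored parameters (self-consistency)."""
        z2 = np.zeros(stack.grid.shape)
        for name in self.niche_vars:
            mean, sd = self.layer_stats[name]
            z = (stack.layers[name] - mean) / sd
            z2 += (z - self.mu[name]) ** 2 / (2.0 * self.sigma[name] ** 2)
        return np.exp(-z2)

    @property
    def range_size(self) -> int:
        return int(self.true_range.sum())


@dataclass
class OccurrenceSet:
    """Occurrence records for one species; grid_cells is filled by data_prep."""

    species_id: str
    records: list[tuple[float, float]]
    grid_cells: np.ndarray | None = None


@dataclass
class NicheConfig:
    """Ranges the virtual-species generator draws niche parameters from.

    sigma is in units of the standardized layers (1 = one baseline sd of the
    climate variable); tau is the suitability level delimiting the range.
    """

    n_vars: tuple[int, int] = (2, 3)
    sigma_range: tuple[float, float] = (0.6, 1.4)
    tau_range: tuple[float, float] = (0.4, 0.8)
    max_retries: int = 120
    # Endemism is climatic, not just administrative: a drawn niche is accepted
    # only if at least this fraction of its suitable cells (suitability >= tau,
    # grid-wide) lies inside the species' country. If no draw reaches the
    # fraction within the retry budget, the most-concentrated qualifying draw
    # is kept, so generation always succeeds.
    min_endemic_fraction: float = 0.9
    # Ranges smaller than this cannot support the modelling pipeline's
    # unique-record floor; draws below it are rejected like empty ranges.
    min_range_cells: int = 30


# ---------------------------------------------------------------------------
# climate generation
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, grid: GridSpec, length: float) -> np.ndarray:
    """Standardized low-pass-filtered Gaussian noise with the given length."""
    raw = rng.standard_normal(grid.shape)
    f = ndimage.gaussian_filter(raw, sigma=length, mode="wrap")
    return (f - f.mean()) / max(f.std(), 1e-12)


def generate_climate(
    grid: GridSpec,
    autocorr_length: float = 3.0,
    cross_corr: float = 0.85,
    seed: int = 0,
) -> ClimateStack:
    """Generate the 19-layer baseline climate stack.

    Each layer is ``sqrt(cross_corr) * family_latent + sqrt(1-cross_corr) *
    own_noise``, all fields smoothed to the requested autocorrelation length,
    so same-family layer pairs have correlation ~= cross_corr. Layers are then
    mapped to plausible bioclim units. Deterministic given the seed.
    """
    if autocorr_length < 1:
        raise ValueError("autocorr_length must be >= 1 cell")
    if not (0 <= cross_corr < 1):
        raise ValueError("cross_corr must lie in [0, 1)")
    if min(grid.n_rows, grid.n_cols) < 4 * autocorr_length:
        raise ValueError(
            f"grid {grid.shape} too small for autocorr_length={autocorr_length}; "
            "need at least 4x the correlation length per side"
        )
    latents = {
        "temperature": _smooth_field(
            np.random.default_rng(subseed(seed, "latent", "temperature")), grid, autocorr_length
        ),
        "precipitation": _smooth_field(
            np.random.default_rng(subseed(seed, "latent", "precipitation")), grid, autocorr_length
        ),
    }
    layers: dict[str, np.ndarray] = {}
    for name in BIOCLIM_LAYERS:
        family = "temperature" if name in TEMPERATURE_LAYERS else "precipitation"
        members = TEMPERATURE_LAYERS if family == "temperature" else PRECIPITATION_LAYERS
        # Heterogeneous latent coupling: the leading layers of a family share
        # the latent at strength cross_corr, trailing ones progressively less
        # (down to 20%), so pairwise correlations span a realistic range —
        # the strongest pairs sit near cross_corr while trailing pairs stay
        # moderate, as in real bioclim data.
        pos = members.index(name) / max(len(members) - 1, 1)
        c = cross_corr * (1.0 - 0.8 * pos)
        own = _smooth_field(np.random.default_rng(subseed(seed, "layer", name)), grid, autocorr_length)
        z = np.sqrt(c) * latents[family] + np.sqrt(1.0 - c) * own
        z = (z - z.mean()) / max(z.std(), 1e-12)
        offset, scale = _LAYER_UNITS[name]
        layers[name] = offset + scale * z
    return ClimateStack(grid, layers, BASELINE, "T0")


def stack_distance(a: ClimateStack, b: ClimateStack, stats: dict | None = None) -> float:
    """Mean per-cell Euclidean distance between stacks in standardized space."""
    if stats is None:
        stats = a.layer_stats()
    sq = np.zeros(a.grid.shape)
    for name in a.layer_names:
        _, sd = stats[name]
        sq += ((b.layers[name] - a.layers[name]) / sd) ** 2
    return float(np.sqrt(sq).mean())


def generate_scenarios(
    baseline: ClimateStack,
    control_shift: dict[str, float],
    melting_shift: dict[str, float],
    horizons: int = 3,
    seed: int = 0,
) -> list[ClimateStack]:
    """Build the control and melting scenario families.

    Shifts are per-layer drift magnitudes in baseline-sd units, reached at the
    final horizon; horizon k receives the fraction k/horizons of the full
    drift, so drift accumulates monotonically. The melting family must be
    strictly more dissimilar from the baseline than the control family; this
    is validated on the supplied shifts and re-asserted on the generated
    stacks at every horizon.
    """
    unknown = (set(control_shift) | set(melting_shift)) - set(baseline.layer_names)
    if unknown:
        raise ValueError(f"shift refers to unknown layers: {sorted(unknown)}")

    def norm(shift: dict[str, float]) -> float:
        return float(np.sqrt(sum(v * v for v in shift.values())))

    if control_shift or melting_shift:
        if norm(melting_shift) <= norm(control_shift):
            raise ValueError(
                "melting_shift must be strictly more dissimilar from baseline "
                f"than control_shift (|melting|={norm(melting_shift):.3f} <= "
                f"|control|={norm(control_shift):.3f})"
            )
    stats = baseline.layer_stats()
    stacks: list[ClimateStack] = []
    for family, shift in ((CONTROL, control_shift), (MELTING, melting_shift)):
        for k in range(1, horizons + 1):
            frac = k / horizons
            layers = {}
            for name, arr in baseline.layers.items():
                _, sd = stats[name]
                layers[name] = arr + frac * shift.get(name, 0.0) * sd
            stacks.append(ClimateStack(baseline.grid, layers, family, f"T{k}"))
    # enforced postcondition: dissimilarity ordering at every horizon
    if control_shift or melting_shift:
        for k in range(1, horizons + 1):
            d_ctl = stack_distance(baseline, _pick(stacks, CONTROL, f"T{k}"), stats)
            d_mlt = stack_distance(baseline, _pick(stacks, MELTING, f"T{k}"), stats)
            if not d_mlt > d_ctl:
                raise ValueError(
                    f"dissimilarity ordering violated at T{k}: melting {d_mlt:.4f} "
                    f"<= control {d_ctl:.4f}"
                )
    return stacks


def _pick(stacks: list[ClimateStack], scenario: str, horizon: str) -> ClimateStack:
    for s in stacks:
        if s.scenario_id == scenario and s.horizon == horizon:
            return s
    raise KeyError(f"no stack for ({scenario}, {horizon})")


# ---------------------------------------------------------------------------
# world partition
# ---------------------------------------------------------------------------

def generate_world(
    grid: GridSpec,
    n_countries: int = 12,
    ecoregions_per_country: int = 3,
    seed: int = 0,
) -> WorldMask:
    """Partition the grid into contiguous countries and nested ecoregions.

    Countries grow by nearest-seed-point assignment (discrete Voronoi), then
    each country is subdivided the same way. All cells are land by default.
    """
    if n_countries < 1:
        raise ValueError("n_countries must be >= 1")
    if n_countries > grid.n_cells:
        raise ValueError(f"more countries ({n_countries}) than cells ({grid.n_cells})")
    rng = np.random.default_rng(subseed(seed, "world"))
    rows, cols = np.indices(grid.shape)
    coords = np.column_stack([rows.ravel(), cols.ravel()]).astype(float)
    seeds = coords[rng.choice(grid.n_cells, size=n_countries, replace=False)]
    # Lloyd relaxation evens out country sizes (nearest-seed growth from raw
    # random seeds yields occasional slivers too small to host endemics)
    for _ in range(10):
        d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)
        for j in range(n_countries):
            sel = coords[assign == j]
            if sel.size:
                seeds[j] = sel.mean(axis=0)
    d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    country = d2.argmin(axis=1).astype(np.int64) + 1  # ties -> lowest country id

    ecoregion = np.zeros(grid.n_cells, dtype=np.int64)
    next_id = 1
    for c in range(1, n_countries + 1):
        idx = np.flatnonzero(country == c)
        k = min(ecoregions_per_country, idx.size)
        sub_rng = np.random.default_rng(subseed(seed, "ecoregions", c))
        sub_seeds = coords[idx[sub_rng.choice(idx.size, size=k, replace=False)]]
        sd2 = ((coords[idx, None, :] - sub_seeds[None, :, :]) ** 2).sum(axis=2)
        ecoregion[idx] = next_id + sd2.argmin(axis=1)
        next_id += k
    return WorldMask(
        grid,
        country.reshape(grid.shape),
        ecoregion.reshape(grid.shape),
        n_countries,
    )


# ---------------------------------------------------------------------------
# virtual species and occurrences
# ---------------------------------------------------------------------------

def generate_virtual_species(
    stack: ClimateStack,
    mask: WorldMask,
    n_species: int,
    niche_config: NicheConfig | None = None,
    seed: int = 0,
    species_per_country: dict[int, int] | None = None,
) -> list[VirtualSpecies]:
    """Draw virtual endemic species with Gaussian niches on the baseline.

    Each species is endemic to one country. Its niche optimum is anchored at
    the (standardized) climate of a randomly chosen cell of that country, so
    suitability 1 is attained inside the country and the true range is never
    empty for tau < 1. Species whose range would still come out empty are
    re-drawn up to ``niche_config.max_retries`` times.

    ``species_per_country`` overrides the default round-robin allocation of
    ``n_species`` across countries (per-country endemic richness is a study
    input, not something the generator invents).
    """
    cfg = niche_config or NicheConfig()
    stats = stack.layer_stats()
    if species_per_country is None:
        countries = [c for c in range(1, mask.country_count + 1)]
        species_per_country = {c: 0 for c in countries}
        for i in range(n_species):
            species_per_country[countries[i % len(countries)]] += 1

    z_layers = {
        name: (stack.layers[name] - stats[name][0]) / stats[name][1]
        for name in stack.layer_names
    }
    # Anchors are biased toward country interiors: endemic ranges centered
    # well inside a country stay inside it, matching how narrow endemics sit
    # within (not across) political/ecoregional units.
    border_dist = {}
    for c in range(1, mask.country_count + 1):
        inside = mask.country_id == c
        dist = ndimage.distance_transform_cdt(inside, metric="chessboard")
        border_dist[c] = dist

    species: list[VirtualSpecies] = []
    idx = 0
    for country, count in sorted(species_per_country.items()):
        cells = mask.country_cells(country)
        if count > 0 and cells.size < 25:
            raise ValueError(
                f"country {country} has only {cells.size} land cells (< 25); "
                "cannot host endemic species"
            )
        for _ in range(count):
            sp_id = f"sp{idx:04d}"
            rng = np.random.default_rng(subseed(seed, "species", sp_id))
            sp = None
            fallback_sp = None  # best non-empty draw below the size floor
            fallback_size = 0
            best_fraction = -1.0
            for _attempt in range(cfg.max_retries):
                k = int(rng.integers(cfg.n_vars[0], cfg.n_vars[1] + 1))
                # Niches combine a thermal and a moisture constraint, as real
                # climatic niches do, and act through the weakly latent-coupled
                # members of each family — the quasi-independent climate axes —
                # rather than through near-duplicate derived variables.
                temp_pool = [n for n in TEMPERATURE_LAYERS[5:] if n in stack.layers]
                prec_pool = [n for n in PRECIPITATION_LAYERS[4:] if n in stack.layers]
                nvars = [str(rng.choice(temp_pool)), str(rng.choice(prec_pool))]
                pool = [n for n in temp_pool + prec_pool if n not in nvars]
                if k > 2 and pool:
                    nvars += rng.choice(pool, size=min(k - 2, len(pool)), replace=False).tolist()
                nvars = sorted(nvars)
                # draw a few candidate anchors, keep the most interior one
                cand = cells[rng.integers(cells.size, size=4)]
                crows, ccols = stack.grid.unravel(cand)
                anchor = int(cand[np.argmax(border_dist[country][crows, ccols])])
                ar, ac = stack.grid.unravel(anchor)
                mu = {v: float(z_layers[v][ar, ac]) for v in nvars}
                sigma = {v: float(rng.uniform(*cfg.sigma_range)) for v in nvars}
                z2 = np.zeros(stack.grid.shape)
                for v in nvars:
                    z2 += (z_layers[v] - mu[v]) ** 2 / (2.0 * sigma[v] ** 2)
                suit = np.exp(-z2)
                in_country = mask.country_id == country
                # The occupancy threshold is the most endemism-relevant knob:
                # pick the lowest tau in range for which the suitable set is
                # both concentrated in the country and large enough, so drawn
                # niches are genuinely endemic rather than label-clipped.
                min_cells = min(cfg.min_range_cells, cells.size)
                for tau in np.linspace(*cfg.tau_range, 9):
                    tau = float(tau)
                    suitable = suit >= tau
                    rng_mask = suitable & in_country
                    size = int(rng_mask.sum())
                    if size == 0:
                        break  # higher tau only shrinks the range further
                    candidate = VirtualSpecies(
                        species_id=sp_id,
                        country_id=country,
                        niche_vars=nvars,
                        mu=mu,
                        sigma=sigma,
                        tau=tau,
                        layer_stats={v: stats[v] for v in nvars},
                        true_suitability=suit,
                        true_range=rng_mask,
                    )
                    if size < min_cells:
                        if size > fallback_size:
                            fallback_sp, fallback_size = candidate, size
                        break
                    fraction = size / float(suitable.sum())
                    if fraction > best_fraction:
                        best_fraction = fraction
                        sp = candidate
                    if fraction >= cfg.min_endemic_fraction:
                        break
                if best_fraction >= cfg.min_endemic_fraction:
                    break
            if sp is None:
                sp = fallback_sp
            if sp is None:
                raise RuntimeError(
                    f"could not draw a species with non-empty range in country "
                    f"{country} after {cfg.max_retries} retries"
                )
            species.append(sp)
            idx += 1
    return species


def sample_occurrences(
    sp: VirtualSpecies,
    mask: WorldMask,
    n: int = 300,
    detection_noise: float = 0.0,
    seed: int = 0,
) -> OccurrenceSet:
    """Sample occurrence records from a species' true range.

    Cells are drawn (with replacement) with probability proportional to true
    suitability inside the true range. With probability ``detection_noise`` a
    record is displaced to a uniformly random cell of the species' country —
    uniform label noise, no spatial sampling-bias model.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= detection_noise <= 1):
        raise ValueError("detection_noise must lie in [0, 1]")
    rng = np.random.default_rng(subseed(seed, "occ", sp.species_id))
    grid = mask.grid
    range_cells = np.flatnonzero(sp.true_range.ravel())
    weights = sp.true_suitability.ravel()[range_cells]
    weights = weights / weights.sum()
    draws = rng.choice(range_cells, size=n, replace=True, p=weights)
    noisy = rng.random(n) < detection_noise
    if noisy.any():
        country_cells = mask.country_cells(sp.country_id)
        draws = draws.copy()
        draws[noisy] = country_cells[rng.integers(country_cells.size, size=int(noisy.sum()))]
    records = []
    rows, cols = grid.unravel(draws)
    for r, c in zip(rows, cols):
        records.append(grid.cell_center(int(r), int(c)))
    return OccurrenceSet(species_id=sp.species_id, records=records)


# ---------------------------------------------------------------------------
# writers (plain-text formats)
# ---------------------------------------------------------------------------

def write_climate_stack(stack: ClimateStack, directory) -> list[str]:
    """Write one ASCII grid per layer, named ``{scenario}_{horizon}_{layer}.asc``."""
    import os

    from .grids import write_ascii_grid

    os.makedirs(directory, exist_ok=True)
    paths = []
    for name, arr in stack.layers.items():
        path = os.path.join(directory, f"{stack.scenario_id}_{stack.horizon}_{name}.asc")
        write_ascii_grid(path, stack.grid, arr)
        paths.append(path)
    return paths


def write_world_mask(mask: WorldMask, directory) -> list[str]:
    """Write country and ecoregion ids as two integer ASCII grids."""
    import os

    from .grids import write_ascii_grid

    os.makedirs(directory, exist_ok=True)
    paths = []
    for name, arr in (("country_id", mask.country_id), ("ecoregion_id", mask.ecoregion_id)):
        path = os.path.join(directory, f"{name}.asc")
        write_ascii_grid(path, mask.grid, arr.astype(float))
        paths.append(path)
    return paths


def write_occurrences(occ_sets: list[OccurrenceSet], path) -> None:
    """Write occurrence records as CSV with header species_id,lon,lat."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["species_id", "lon", "lat"])
        for occ in occ_sets:
            for lon, lat in occ.records:
                writer.writerow([occ.species_id, repr(lon), repr(lat)])


def read_occurrences(path) -> list[OccurrenceSet]:
    """Read an occurrence CSV back into per-species OccurrenceSets."""
    import csv

    by_sp: dict[str, list[tuple[float, float]]] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh):
            by_sp.setdefault(row["species_id"], []).append(
                (float(row["lon"]), float(row["lat"]))
            )
    return [OccurrenceSet(sp, recs) for sp, recs in by_sp.items()]


def write_species_truth(species: list[VirtualSpecies], path) -> None:
    """Write niche parameters and true range sizes as CSV."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["species_id", "country_id", "niche_vars", "mu", "sigma", "tau", "true_range_size"]
        )
        for sp in species:
            writer.writerow(
                [
                    sp.species_id,
                    sp.country_id,
                    ";".join(sp.niche_vars),
                    ";".join(repr(sp.mu[v]) for v in sp.niche_vars),
                    ";".join(repr(sp.sigma[v]) for v in sp.niche_vars),
                    repr(sp.tau),
                    sp.range_size,
                ]
            )
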