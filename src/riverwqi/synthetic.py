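"""Synthetic river-monitoring scenarios: layout, plumes, noise.

The generator emulates the statistical and spatial structure the
assessment pipeline assumes, so every stage is testable without field
data:

* a sampling **layout** of sites spaced along a straight river corridor,
  each subdivided into main-channel / east / west lateral points (the
  shipped presets use 8 sites and 18 points, sector pattern
  3-3-1-3-3-1-1-3, on a 120 km reach);
* seasonal **baselines** per parameter (background water within
  regulatory limits, low summer dissolved oxygen, cool winter
  temperatures);
* industrial-discharge **hotspots**: isotropic exponential plumes,
  ``amplitude * exp(-distance / decay_length)``, added to the affected
  parameters for the seasons the plant operates (sugar mills run in
  winter only; the paper mill year-round; the ferroalloy plant releases
  only low-heat cooling water, so it perturbs temperature alone);
* deterministic **couplings**: BOD drawn as ratio*COD with the ratio
  uniform in a configurable band (default 0.5-0.7, the biodegradable
  range), and DO depressed proportionally to the local organic load
  above background;
* measurement **noise**: multiplicative mean-one log-normal with a
  per-parameter coefficient of variation for concentrations (positive,
  right-skewed), additive Gaussian for pH and temperature.

Everything is deterministic given (scenario, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .core import ConfigError, Dataset, SampleRecord, SamplingSite
from .idw import to_geographic, project_coords

PRESET_NAMES = ("aswan2024", "clean_river", "single_hotspot")


@dataclass(frozen=True)
class Hotspot:
    """One effluent discharge: an exponential plume on affected parameters."""

    name: str
    along_m: float  # position along the corridor (northwards)
    across_m: float  # lateral position (eastwards, 0 = main channel)
    decay_m: float
    affected: dict[str, float]  # parameter -> amplitude at distance 0
    seasons: tuple[str, ...] = ("summer", "winter")

    def __post_init__(self) -> None:
        if not self.decay_m > 0:
            raise ConfigError(f"hotspot {self.name!r}: decay length must be > 0")
        for p, a in self.affected.items():
            if not math.isfinite(a):
                raise ConfigError(f"hotspot {self.name!r}: amplitude for {p!r} "
                                  "is not finite")


@dataclass(frozen=True)
class SiteSpec:
    """One site of the layout: corridor position and lateral sectors."""

    site_id: str
    along_km: float
    sectors: tuple[str, ...] = ("main", "east", "west")
    city: str = ""
    description: str = ""


@dataclass(frozen=True)
class Scenario:
    """Full specification of a synthetic monitoring campaign."""

    name: str
    sites: tuple[SiteSpec, ...]
    corridor_km: float
    baselines: dict[str, dict[str, float]]  # parameter -> {season: mean}
    noise_cv: dict[str, float] = field(default_factory=dict)
    additive_sd: dict[str, float] = field(default_factory=dict)
    hotspots: tuple[Hotspot, ...] = ()
    bod_cod_ratio: tuple[float, float] | None = None
    do_decrement_per_cod: float | None = None
    origin: tuple[float, float] = (32.90, 23.97)  # (lon, lat) of corridor start
    lateral_offset_m: float = 250.0
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.corridor_km > 0:
            raise ConfigError("corridor length must be positive")
        if len(self.sites) < 2:
            raise ConfigError("a scenario needs at least two sites")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        for p, cv in self.noise_cv.items():
            if cv < 0:
                raise ConfigError(f"noise CV for {p!r} must be >= 0")
        if self.bod_cod_ratio is not None:
            lo, hi = self.bod_cod_ratio
            if not (0 <= lo <= hi):
                raise ConfigError("bod_cod_ratio band must satisfy 0 <= lo <= hi")
            if "COD" not in self.baselines or "BOD" not in self.baselines:
                raise ConfigError(
                    "BOD/COD coupling requires both parameters in baselines"
                )

    @property
    def parameters(self) -> list[str]:
        return list(self.baselines)


# ---------------------------------------------------------------------------
# Layout


def generate_layout(scenario: Scenario) -> list[SamplingSite]:
    """Sampling points of the scenario, as geographic sites.

    Sites sit on a straight south-to-north corridor at their specified
    along-river positions; east/west sectors are offset laterally by
    ``lateral_offset_m``.  Purely deterministic.
    """
    offsets = {"main": 0.0, "east": scenario.lateral_offset_m,
               "west": -scenario.lateral_offset_m}
    sites: list[SamplingSite] = []
    for spec in scenario.sites:
        if not 0 <= spec.along_km <= scenario.corridor_km:
            raise ConfigError(
                f"site {spec.site_id!r} lies outside the {scenario.corridor_km} km "
                "corridor"
            )
        for sector in spec.sectors:
            x = offsets[sector]
            y = spec.along_km * 1000.0
            lon, lat = to_geographic(x, y, scenario.origin)
            sites.append(
                SamplingSite(
                    site_id=spec.site_id,
                    sector=sector,
                    longitude=float(lon),
                    latitude=float(lat),
                    city=spec.city,
                    description=spec.description,
                )
            )
    return sites


def planar_points(scenario: Scenario, sites: list[SamplingSite]) -> np.ndarray:
    """(N, 2) planar metres (across, along) of the layout points."""
    lons = np.array([s.longitude for s in sites])
    lats = np.array([s.latitude for s in sites])
    x, y = project_coords(lons, lats, origin=scenario.origin)
    return np.column_stack([x, y])


def point_hotspot_distance(
    scenario: Scenario, sites: list[SamplingSite] | None = None
) -> np.ndarray:
    """(N, H) matrix of point-to-hotspot distances in metres."""
    if sites is None:
        sites = generate_layout(scenario)
    pts = planar_points(scenario, sites)
    if not scenario.hotspots:
        return np.empty((len(pts), 0))
    hs = np.array([[h.across_m, h.along_m] for h in scenario.hotspots])
    return np.sqrt(((pts[:, None, :] - hs[None, :, :]) ** 2).sum(axis=2))


def nearest_point_to_hotspot(
    scenario: Scenario, hotspot_name: str
) -> tuple[str, str]:
    """(site_id, sector) of the sampling point nearest a named hotspot."""
    sites = generate_layout(scenario)
    names = [h.name for h in scenario.hotspots]
    d = point_hotspot_distance(scenario, sites)[:, names.index(hotspot_name)]
    s = sites[int(np.argmin(d))]
    return (s.site_id, s.sector)


def background_points(
    scenario: Scenario, min_distance_m: float = 2500.0
) -> list[tuple[str, str]]:
    """Points farther than ``min_distance_m`` from every hotspot."""
    sites = generate_layout(scenario)
    d = point_hotspot_distance(scenario, sites)
    if d.shape[1] == 0:
        return [s.key for s in sites]
    keep = d.min(axis=1) > min_distance_m
    return [s.key for s, k in zip(sites, keep) if k]


# ---------------------------------------------------------------------------
# Simulation

_ADDITIVE_DEFAULT = ("pH", "temperature")


def _plume(scenario: Scenario, dists: np.ndarray, season: str, param: str) -> float:
    total = 0.0
    for j, h in enumerate(scenario.hotspots):
        if season in h.seasons and param in h.affected:
            total += h.affected[param] * math.exp(-dists[j] / h.decay_m)
    return total


def _clamp(param: str, value: float) -> float:
    if param == "pH":
        return min(max(value, 0.0), 14.0)
    if param == "temperature":
        return value
    if param == "DO":
        return max(value, 0.05)
    return max(value, 0.0)


def simulate_dataset(scenario: Scenario, seed: int | None = None) -> Dataset:
    """Draw one synthetic Dataset from the scenario.

    For each point, season and parameter: value = seasonal baseline +
    sum of active hotspot plumes, then the BOD/COD and DO couplings,
    then measurement noise, then clamping to the physical domain.
    Deterministic given (scenario, seed); the seed used is recorded in
    the Dataset provenance.
    """
    used_seed = scenario.seed if seed is None else seed
    rng = np.random.default_rng(used_seed)
    sites = generate_layout(scenario)
    dists = point_hotspot_distance(scenario, sites)
    params = scenario.parameters
    records: list[SampleRecord] = []
    for season in ("summer", "winter"):
        for p_idx, site in enumerate(sites):
            # noiseless field at this point
            clean: dict[str, float] = {}
            for param in params:
                try:
                    base = scenario.baselines[param][season]
                except KeyError:
                    raise ConfigError(
                        f"baseline for {param!r} missing season {season!r}"
                    ) from None
                clean[param] = base + _plume(scenario, dists[p_idx], season, param)
            if scenario.do_decrement_per_cod is not None and "DO" in clean:
                organic_excess = clean.get("COD", 0.0) - scenario.baselines.get(
                    "COD", {}
                ).get(season, 0.0)
                clean["DO"] -= scenario.do_decrement_per_cod * max(organic_excess, 0.0)
            for rep in range(scenario.replicates):
                values = dict(clean)
                if scenario.bod_cod_ratio is not None:
                    lo, hi = scenario.bod_cod_ratio
                    ratio = rng.uniform(lo, hi)
                    values["BOD"] = ratio * values["COD"]
                for param in params:
                    v = values[param]
                    if param in scenario.additive_sd:
                        sd = scenario.additive_sd[param]
                        if sd > 0:
                            v += rng.normal(0.0, sd)
                    else:
                        cv = scenario.noise_cv.get(param, 0.0)
                        if cv > 0:
                            sigma = math.sqrt(math.log1p(cv * cv))
                            v *= math.exp(rng.normal(0.0, sigma) - 0.5 * sigma * sigma)
                    records.append(
                        SampleRecord(
                            site_id=site.site_id,
                            sector=site.sector,
                            season=season,
                            parameter=param,
                            value=_clamp(param, v),
                            replicate=rep,
                        )
                    )
    return Dataset(
        sites=sites,
        records=records,
        provenance=f"scenario:{scenario.name} seed:{used_seed}",
    )


# ---------------------------------------------------------------------------
# Presets (shipped as editable YAML)


def _scenario_dir() -> Path:
    return Path(str(resources.files("riverwqi") / "data" / "scenarios"))


def scenario_from_dict(doc: dict) -> Scenario:
    """Build a Scenario from a parsed configuration mapping."""
    try:
        layout = doc["layout"]
        baselines = doc["baselines"]
    except KeyError as exc:
        raise ConfigError(f"scenario config missing section {exc}") from None
    sites = tuple(
        SiteSpec(
            site_id=s["site_id"],
            along_km=float(s["along_km"]),
            sectors=tuple(s.get("sectors", ("main", "east", "west"))),
            city=s.get("city", ""),
            description=s.get("description", ""),
        )
        for s in layout["sites"]
    )
    hotspots = tuple(
        Hotspot(
            name=h["name"],
            along_m=float(h["along_km"]) * 1000.0,
            across_m=float(h.get("across_m", 0.0)),
            decay_m=float(h.get("decay_m", 500.0)),
            affected={k: float(v) for k, v in h["affected"].items()},
            seasons=tuple(h.get("seasons", ("summer", "winter"))),
        )
        for h in doc.get("hotspots", [])
    )
    couplings = doc.get("couplings", {}) or {}
    ratio = couplings.get("bod_from_cod_ratio")
    origin = layout.get("origin", {})
    return Scenario(
        name=doc.get("name", "custom"),
        sites=sites,
        corridor_km=float(layout["corridor_km"]),
        baselines={
            p: {s: float(v) for s, v in seasons.items()}
            for p, seasons in baselines.items()
        },
        noise_cv={p: float(v) for p, v in (doc.get("noise_cv") or {}).items()},
        additive_sd={
            p: float(v) for p, v in (doc.get("additive_noise_sd") or {}).items()
        },
        hotspots=hotspots,
        bod_cod_ratio=(float(ratio[0]), float(ratio[1])) if ratio else None,
        do_decrement_per_cod=(
            float(couplings["do_decrement_per_cod"])
            if couplings.get("do_decrement_per_cod") is not None
            else None
        ),
        origin=(float(origin.get("lon", 32.90)), float(origin.get("lat", 23.97))),
        lateral_offset_m=float(layout.get("lateral_offset_m", 250.0)),
        replicates=int(doc.get("replicates", 3)),
        seed=int(doc.get("seed", 0)),
    )


def scenario_from_file(path: str | Path) -> Scenario:
    with open(path, "r", encoding="utf-8") as fh:
        return scenario_from_dict(yaml.safe_load(fh))


def preset_scenario(name: str) -> Scenario:
    """One of the shipped presets: aswan2024, clean_river, single_hotspot."""
    if name not in PRESET_NAMES:
        raise ConfigError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        )
    return scenario_from_file(_scenario_dir() / f"{name}.yaml")


def with_overrides(scenario: Scenario, **kwargs) -> Scenario:
    """A copy of the scenario with selected fields replaced."""
    return replace(scenario, **kwargs)
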