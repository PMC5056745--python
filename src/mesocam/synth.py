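"""Synthetic camera-trap surveys with known ground truth.

The generator emulates the design of a multi-year baited camera-trap survey
in mountainous Southwest China: stations on a grid around a study-area
centroid, four-to-six-week deployments with scent lure applied at setup, a
small guild of focal species with distinct diel archetypes (nocturnal,
diurnal, crepuscular, arrhythmic), seasonal detection-rate variation
(including complete winter dormancy), and pairwise site co-occurrence
governed by a species interaction factor gamma.

Detection is simulated at the *event* level: an occupied site-species
produces events as an inhomogeneous Poisson process (daily rate x monthly
multiplier), each event gets a sun-time drawn from the species' von Mises
mixture and is converted to clock time through the station's actual solar
schedule.  The analysis pipeline then collapses events to occasions itself,
exercising the same code paths as real data.  The per-occasion detection
probability implied by rate lambda over d occasion-days is 1 - exp(-lambda*d),
so configs can target a specific p.

For occupancy-estimator studies a direct per-occasion Bernoulli simulator
(:func:`simulate_detection_histories`) avoids the solar machinery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from mesocam.cooccur import DetectionHistoryPair
from mesocam.errors import ConfigurationError
from mesocam.solar import diel_schedule, from_sun_time

TWO_PI = 2.0 * np.pi


@dataclass
class SpeciesConfig:
    """One focal species: occupancy, detection rate, diel and seasonal shape."""
    name: str
    psi: float
    daily_rate: float                      # events per occupied camera-day
    diel_means_h: tuple = (12.0,)          # mixture means, sun-time hours
    diel_kappas: tuple = (1.0,)
    diel_weights: tuple = (1.0,)
    monthly_multipliers: tuple = (1.0,) * 12

    def __post_init__(self):
        self.diel_means_h = tuple(self.diel_means_h)
        self.diel_kappas = tuple(self.diel_kappas)
        self.diel_weights = tuple(self.diel_weights)
        self.monthly_multipliers = tuple(self.monthly_multipliers)
        if not np.isclose(sum(self.diel_weights), 1.0):
            raise ConfigurationError(f"{self.name}: mixture weights must sum to 1")
        if not 0.0 <= self.psi <= 1.0:
            raise ConfigurationError(f"{self.name}: psi must be in [0, 1]")
        if len(self.monthly_multipliers) != 12:
            raise ConfigurationError(f"{self.name}: need 12 monthly multipliers")


@dataclass
class PairConfig:
    """A focal species pair with its true species interaction factor."""
    species_a: str
    species_b: str
    gamma: float = 1.0


@dataclass
class SynthConfig:
    """Full survey design for :func:`simulate_survey`."""
    n_stations: int = 60
    window_start: str = "2013-03-01"
    window_end: str = "2013-11-30"
    deployment_days_min: float = 28.0
    deployment_days_max: float = 42.0
    centroid_lat: float = 32.9
    centroid_lon: float = 104.1
    coord_jitter_deg: float = 0.35
    tz_hours: float = 8.0
    p_fast_camera: float = 0.6
    duplicate_prob: float = 0.25            # extra photos <30 min after an event
    species: list = field(default_factory=list)
    pairs: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        self.species = [SpeciesConfig(**s) if isinstance(s, dict) else s
                        for s in self.species]
        self.pairs = [PairConfig(**p) if isinstance(p, dict) else p
                      for p in self.pairs]
        by_name = {s.name: s for s in self.species}
        seen = set()
        for pair in self.pairs:
            for sp in (pair.species_a, pair.species_b):
                if sp not in by_name:
                    raise ConfigurationError(f"pair references unknown species {sp!r}")
                if sp in seen:
                    raise ConfigurationError(
                        f"species {sp!r} appears in more than one pair")
                seen.add(sp)
            a, b = by_name[pair.species_a], by_name[pair.species_b]
            joint = pair.gamma * a.psi * b.psi
            if joint > min(a.psi, b.psi) + 1e-12 or joint < max(0.0, a.psi + b.psi - 1.0) - 1e-12:
                raise ConfigurationError(
                    f"gamma={pair.gamma} infeasible for psi=({a.psi}, {b.psi})")

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def simulate_activity_times(archetype, n: int, seed=None) -> np.ndarray:
    """Draw n angles (radians) from a von Mises mixture diel archetype.

    ``archetype`` is a :class:`SpeciesConfig` or any object with
    ``diel_means_h``, ``diel_kappas``, ``diel_weights``.  Means are sun-time
    hours; returned angles are on [0, 2*pi) with 1 h = pi/12.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    means = np.asarray(archetype.diel_means_h, dtype=float) * TWO_PI / 24.0
    kappas = np.asarray(archetype.diel_kappas, dtype=float)
    weights = np.asarray(archetype.diel_weights, dtype=float)
    comp = rng.choice(len(means), size=n, p=weights)
    out = np.empty(n)
    for c in range(len(means)):
        mask = comp == c
        if mask.any():
            out[mask] = rng.vonmises(means[c], kappas[c], size=int(mask.sum()))
    return out % TWO_PI


def _draw_joint_occupancy(cfg: SynthConfig, rng: np.random.Generator) -> dict:
    """Latent presence per (station index, species name)."""
    by_name = {s.name: s for s in cfg.species}
    paired = {p.species_a for p in cfg.pairs} | {p.species_b for p in cfg.pairs}
    z = {}
    for pair in cfg.pairs:
        a, b = by_name[pair.species_a], by_name[pair.species_b]
        p_both = pair.gamma * a.psi * b.psi
        probs = [p_both, a.psi - p_both, b.psi - p_both,
                 1.0 - a.psi - b.psi + p_both]
        states = rng.choice(4, size=cfg.n_stations, p=probs)
        z[pair.species_a] = np.isin(states, [0, 1])
        z[pair.species_b] = np.isin(states, [0, 2])
    for s in cfg.species:
        if s.name not in paired:
            z[s.name] = rng.random(cfg.n_stations) < s.psi
    return z


def simulate_survey(config: SynthConfig, seed: int | None = None):
    """Generate (photos, deployments, truth) for one synthetic survey.

    ``seed`` overrides ``config.seed``.  Output tables use the canonical
    column layouts read by :mod:`mesocam.io_camtrap`; ``truth`` is a
    JSON-serializable record of all latent values.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    w0, w1 = pd.Timestamp(config.window_start), pd.Timestamp(config.window_end)
    window_days = (w1 - w0) / pd.Timedelta(days=1)

    dep_rows = []
    sched_cache: dict = {}
    for i in range(config.n_stations):
        sid = f"ST{i + 1:04d}"
        lat = config.centroid_lat + rng.uniform(-1, 1) * config.coord_jitter_deg
        lon = config.centroid_lon + rng.uniform(-1, 1) * config.coord_jitter_deg
        length = rng.uniform(config.deployment_days_min, config.deployment_days_max)
        start_off = rng.uniform(0, max(window_days - length, 0))
        start = w0 + pd.Timedelta(days=round(start_off * 96) / 96)   # 15-min grid
        end = start + pd.Timedelta(days=round(length * 96) / 96)
        speed = "fast" if rng.random() < config.p_fast_camera else "slow"
        dep_rows.append({"station_id": sid, "latitude": round(lat, 5),
                         "longitude": round(lon, 5), "elevation": None,
                         "start": start, "end": end, "camera_speed": speed,
                         "lure_dates": [start.normalize()]})
    deployments = pd.DataFrame(dep_rows)

    z = _draw_joint_occupancy(config, rng)

    def schedule(lat, lon, day):
        key = (lat, lon, day)
        if key not in sched_cache:
            sched_cache[key] = diel_schedule(lat, lon, day, config.tz_hours)
        return sched_cache[key]

    photo_rows = []
    for i, dep in enumerate(dep_rows):
        for sp in config.species:
            if not z[sp.name][i]:
                continue
            day = dep["start"].normalize()
            while day < dep["end"]:
                mult = sp.monthly_multipliers[day.month - 1]
                lam = sp.daily_rate * mult
                n_ev = rng.poisson(lam) if lam > 0 else 0
                if n_ev:
                    sun_h = simulate_activity_times(sp, n_ev, rng) * 24.0 / TWO_PI
                    s0 = schedule(dep["latitude"], dep["longitude"], day)
                    s1 = schedule(dep["latitude"], dep["longitude"],
                                  day + pd.Timedelta(days=1))
                    for h in sun_h:
                        t = from_sun_time(h, s0, s1).floor("min")
                        if not (dep["start"] <= t < dep["end"]):
                            continue
                        photo_rows.append({"station_id": dep["station_id"],
                                           "species": sp.name, "timestamp": t,
                                           "n_individuals": int(1 + rng.poisson(0.2))})
                        if rng.random() < config.duplicate_prob:
                            t2 = t + pd.Timedelta(minutes=int(rng.integers(1, 29)))
                            if t2 < dep["end"]:
                                photo_rows.append({"station_id": dep["station_id"],
                                                   "species": sp.name,
                                                   "timestamp": t2,
                                                   "n_individuals": 1})
                day += pd.Timedelta(days=1)
    photos = (pd.DataFrame(photo_rows,
                           columns=["station_id", "species", "timestamp",
                                    "n_individuals"])
              .sort_values(["station_id", "species", "timestamp"])
              .reset_index(drop=True))

    truth = {
        "seed": int(config.seed if seed is None else seed),
        "occupancy": {sp: [bool(v) for v in z[sp]] for sp in z},
        "stations": [d["station_id"] for d in dep_rows],
        "pairs": [asdict(p) for p in config.pairs],
        "species": [asdict(s) for s in config.species],
    }
    return photos, deployments, truth


def simulate_detection_histories(psi_a: float, psi_b: float, gamma: float,
                                 p: float, r: float, n_sites: int,
                                 n_occasions: int, seed=None,
                                 ) -> tuple[DetectionHistoryPair, dict]:
    """Direct per-occasion Bernoulli simulation of a two-species history.

    Detection probability is ``p`` for a species alone at a site and ``r``
    where both species are present (scalar, no covariates).  Returns the
    history and a truth dict with the latent states.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_both = gamma * psi_a * psi_b
    if p_both > min(psi_a, psi_b) + 1e-12 or p_both < max(0.0, psi_a + psi_b - 1.0):
        raise ConfigurationError("infeasible gamma for given psi values")
    probs = [p_both, psi_a - p_both, psi_b - p_both, 1 - psi_a - psi_b + p_both]
    latent = rng.choice(4, size=n_sites, p=probs)      # 0 both, 1 A, 2 B, 3 none
    pres_a = np.isin(latent, [0, 1])[:, None]
    pres_b = np.isin(latent, [0, 2])[:, None]
    both = (latent == 0)[:, None]
    det_prob_a = np.where(both, r, p)
    det_prob_b = np.where(both, r, p)
    det_a = pres_a & (rng.random((n_sites, n_occasions)) < det_prob_a)
    det_b = pres_b & (rng.random((n_sites, n_occasions)) < det_prob_b)
    states = np.zeros((n_sites, n_occasions), dtype=int)
    states[det_a & ~det_b] = 1
    states[~det_a & det_b] = 2
    states[det_a & det_b] = 3
    hist = DetectionHistoryPair(
        sites=[f"S{i:04d}" for i in range(n_sites)], states=states,
        lure_bin=np.zeros_like(states), cam_slow=np.zeros_like(states),
        species_a="A", species_b="B")
    truth = {"psi_a": psi_a, "psi_b": psi_b, "gamma": gamma, "p": p, "r": r,
             "latent": latent.tolist()}
    return hist, truth


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)


def minshan_mini_config() -> SynthConfig:
    """The shipped fast-test fixture: 60 stations, 4 species, 2 focal pairs."""
    from importlib.resources import files
    return SynthConfig.from_yaml(files("mesocam.configs") / "minshan_mini.yaml")
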