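"""Synthetic mesocosm generator with planted ground truth.

Emulates the statistical structure of a two-soil mesocosm experiment: 13
annual plant censuses with a species-invasion onset partway through, a soil
chemistry table driven by plant community summaries through a known
standardized path-coefficient structure, and paired prokaryote/fungal OTU
count tables with planted network-cluster blocks, a tunable per-soil
prokaryote-fungal coupling, and planted habitat specialists.

Counts arise from a log-normal latent-abundance model pushed through a
multinomial conditioned on a negative-binomial sequencing depth, so
per-sample totals match the drawn depth exactly and the data are genuinely
compositional — what the clr-based network inference assumes.  Coupling is
planted at the level of rank-matched cluster latent factors: prokaryote
cluster k and fungal cluster k share a latent factor with correlation
``coupling_rho`` in each soil, mirroring how the coupling beta pairs
clusters by prevalence rank downstream.

Everything is driven by one integer seed; identical (config, seed) yields
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .otutable import OtuTable

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "default_path_coefficients",
    "generate_dataset",
    "generate_plant_series",
    "generate_otu_counts",
]

SOILS = ("natural", "abandoned")
CHEM_VARS = [
    "total_n", "organic_c", "ph", "avail_p", "no3", "nh4", "no2",
    "belowground_productivity",
]
CHEM_UNITS = {  # plausible field means/sds for the output table
    "total_n": (2.5, 0.5), "organic_c": (30.0, 5.0), "ph": (5.5, 0.4),
    "avail_p": (12.0, 3.0), "no3": (8.0, 2.0), "nh4": (4.0, 1.0),
    "no2": (0.15, 0.05), "belowground_productivity": (250.0, 60.0),
}


def default_path_coefficients() -> dict:
    """Chemistry-mediated (indirect-dominant) default path structure.

    Keys: ``plant_chem`` maps (plant parameter, chemical) to a standardized
    beta; ``chem_microbe`` maps (chemical, (domain, cluster)) and
    ``plant_microbe`` maps (plant parameter, (domain, cluster)) likewise.
    """
    return {
        "plant_chem": {
            ("productivity", "total_n"): 0.5,
            ("diversity", "organic_c"): -0.4,
            ("axis1", "ph"): 0.5,
            ("impact_productivity", "no3"): 0.4,
            ("trajectory_diversity", "nh4"): 0.4,
            ("impact_axis1", "avail_p"): 0.4,
        },
        "chem_microbe": {
            ("total_n", ("prokaryote", 1)): 0.5,
            ("ph", ("fungal", 1)): 0.5,
            ("organic_c", ("prokaryote", 2)): -0.4,
        },
        "plant_microbe": {},
    }


@dataclass
class SyntheticConfig:
    n_mesocosms_per_soil: int = 30
    years: tuple[int, int] = (2007, 2019)
    invasion_onset_year: int = 2012
    n_sown_species: int = 12
    n_invader_species: int = 8
    n_prok_otus: int = 150
    n_fungal_otus: int = 150
    n_prok_clusters: int = 5
    n_fungal_clusters: int = 5
    coupling_rho_per_soil: dict = field(
        default_factory=lambda: {"natural": 0.4, "abandoned": 0.4}
    )
    specialist_fraction: float = 0.2
    specialist_fold_change: float = 8.0
    depth_mean: float = 5000.0
    depth_dispersion: float = 10.0  # negative-binomial size of the depth draw
    nb_dispersion: float = 0.3  # per-sample log-normal OTU noise sd (overdispersion)
    cluster_signal_sd: float = 0.8
    otu_effect_sd: float = 0.5  # fixed per-OTU log-abundance spread within cluster
    path_coefficients: dict = field(default_factory=default_path_coefficients)
    noise_sd: float = 1.0  # chemistry residual scale multiplier
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_mesocosms_per_soil": self.n_mesocosms_per_soil,
            "n_sown_species": self.n_sown_species,
            "n_prok_otus": self.n_prok_otus,
            "n_fungal_otus": self.n_fungal_otus,
            "n_prok_clusters": self.n_prok_clusters,
            "n_fungal_clusters": self.n_fungal_clusters,
        }
        for name, v in counts.items():
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigError(f"{name} must be an integer >= 1, got {v!r}")
        if self.n_invader_species < 0:
            raise ConfigError("n_invader_species must be >= 0")
        y0, y1 = self.years
        if not y0 <= self.invasion_onset_year <= y1:
            raise ConfigError(
                f"invasion_onset_year {self.invasion_onset_year} outside years {self.years}"
            )
        for soil in SOILS:
            if soil not in self.coupling_rho_per_soil:
                raise ConfigError(f"coupling_rho_per_soil missing soil {soil!r}")
            rho = self.coupling_rho_per_soil[soil]
            if not -1 <= rho <= 1:
                raise ConfigError(f"coupling_rho_per_soil[{soil!r}] = {rho} not in [-1, 1]")
        if not 0 <= self.specialist_fraction <= 1:
            raise ConfigError(f"specialist_fraction {self.specialist_fraction} not in [0, 1]")
        if self.specialist_fold_change < 1:
            raise ConfigError(f"specialist_fold_change {self.specialist_fold_change} < 1")
        if self.depth_mean < 1:
            raise ConfigError("depth_mean must be >= 1")
        for name in ("depth_dispersion", "nb_dispersion", "noise_sd",
                     "cluster_signal_sd", "otu_effect_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass
class SyntheticTruth:
    prok_clusters: dict  # OTU id -> planted cluster (1-based)
    fungal_clusters: dict
    prok_specialists: dict  # OTU id -> bool
    fungal_specialists: dict
    coupling_rho_per_soil: dict
    path_coefficients: dict
    axes: pd.DataFrame  # mesocosm_id x year latent compositional axes

    def to_json_dict(self) -> dict:
        pc = {
            k: {f"{a}->{b if isinstance(b, str) else '/'.join(map(str, b))}": v
                for (a, b), v in d.items()}
            for k, d in self.path_coefficients.items()
        }
        return {
            "prok_clusters": self.prok_clusters,
            "fungal_clusters": self.fungal_clusters,
            "prok_specialists": {k: bool(v) for k, v in self.prok_specialists.items()},
            "fungal_specialists": {k: bool(v) for k, v in self.fungal_specialists.items()},
            "coupling_rho_per_soil": self.coupling_rho_per_soil,
            "path_coefficients": pc,
            "axes": self.axes.to_dict(orient="list"),
        }


def _mesocosm_frame(config: SyntheticConfig) -> pd.DataFrame:
    rows = []
    densities = ["low", "mid", "high"]
    i = 0
    for soil in SOILS:
        for m in range(config.n_mesocosms_per_soil):
            i += 1
            rows.append(
                {"mesocosm_id": f"M{i:03d}", "soil": soil,
                 "sowing_density": densities[m % 3]}
            )
    return pd.DataFrame(rows)


def generate_plant_series(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant biomass records plus latent compositional axes.

    Species shares follow a softmax of drifting logits: sown species logits
    concentrate slowly (diversity declines), invader species enter at the
    onset year with their own logits (diversity jumps).  Total productivity
    is year-stationary log-normal noise.  Axes are AR(1) latent series with
    a soil offset and an onset shock on axis 1.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    meso = _mesocosm_frame(config)
    y0, y1 = config.years
    years = list(range(y0, y1 + 1))
    onset = config.invasion_onset_year
    n_s, n_i = config.n_sown_species, config.n_invader_species
    species = [f"sown_{k+1:02d}" for k in range(n_s)] + [
        f"inv_{k+1:02d}" for k in range(n_i)
    ]

    plant_rows = []
    axes_rows = []
    for _, row in meso.iterrows():
        mid, soil = row["mesocosm_id"], row["soil"]
        sown_logit = rng.normal(0.0, 0.8, size=n_s)
        inv_logit = rng.normal(-0.7, 0.5, size=n_i)
        inv_scale = 1.3 if soil == "abandoned" else 1.0  # invaders do better there
        ax = rng.normal(0.0, 0.6, size=3)
        ax_shock = rng.normal(1.0, 0.3)
        soil_off = -0.4 if soil == "natural" else 0.4
        logit = sown_logit.copy()
        for t, year in enumerate(years):
            logit = logit + rng.normal(0.0, 0.15, size=n_s)
            conc = 1.0 + 0.08 * t  # slow dominance build-up
            shares_sown = np.exp(conc * logit)
            if year >= onset and n_i > 0:
                shares_inv = inv_scale * np.exp(
                    inv_logit + rng.normal(0.0, 0.2, size=n_i)
                )
            else:
                shares_inv = np.zeros(n_i)
            shares = np.concatenate([shares_sown, shares_inv])
            shares = shares / shares.sum()
            total = float(np.exp(rng.normal(np.log(600.0), 0.15)))
            for sp, sh in zip(species, shares):
                plant_rows.append(
                    {"mesocosm_id": mid, "soil": soil,
                     "sowing_density": row["sowing_density"], "year": year,
                     "species_id": sp, "invader_flag": sp.startswith("inv_"),
                     "biomass_g": total * sh}
                )
            ax = 0.7 * ax + rng.normal(0.0, 0.3, size=3)
            shock = ax_shock if year >= onset else 0.0
            axes_rows.append(
                {"mesocosm_id": mid, "year": year,
                 "axis1": soil_off + ax[0] + shock,
                 "axis2": ax[1], "axis3": ax[2]}
            )
    return pd.DataFrame(plant_rows), pd.DataFrame(axes_rows)


def generate_otu_counts(
    latent_cluster_abundances: pd.DataFrame,
    otu_clusters,
    depth_mean: float = 5000.0,
    depth_dispersion: float = 10.0,
    nb_dispersion: float = 0.0,
    otu_log_effects: pd.DataFrame | np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Counts from positive latent cluster masses (samples x clusters).

    Each OTU inherits its cluster's mass divided evenly over the cluster,
    modulated by optional per-(sample, OTU) log effects and log-normal noise
    of sd ``nb_dispersion``; read depth per sample is a negative-binomial
    draw (mean ``depth_mean``, size ``depth_dispersion``, floored at 1) and
    counts are a single multinomial conditioned on it, so row sums equal the
    drawn depth exactly.
    """
    lat = latent_cluster_abundances
    arr = lat.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise DataError("latent cluster abundances must be finite and >= 0")
    clusters = np.asarray(otu_clusters, dtype=int)
    n_samples, n_clusters = arr.shape
    n_otus = len(clusters)
    if clusters.min() < 1 or clusters.max() > n_clusters:
        raise DataError("otu cluster labels must be in 1..n_clusters")
    rng = np.random.default_rng(seed)
    sizes = np.bincount(clusters, minlength=n_clusters + 1)[1:]
    mass = arr[:, clusters - 1] / sizes[clusters - 1]
    if otu_log_effects is not None:
        eff = np.asarray(
            otu_log_effects.to_numpy()
            if isinstance(otu_log_effects, pd.DataFrame)
            else otu_log_effects,
            dtype=float,
        )
        mass = mass * np.exp(eff)
    if nb_dispersion > 0:
        mass = mass * np.exp(rng.normal(0.0, nb_dispersion, size=mass.shape))

    # negative-binomial depth: size r, p = r / (r + mean)
    r = depth_dispersion
    if r <= 0:
        depths = np.full(n_samples, int(round(depth_mean)))
    else:
        depths = rng.negative_binomial(r, r / (r + depth_mean), size=n_samples)
    depths = np.maximum(depths, 1)

    counts = np.zeros((n_samples, n_otus), dtype=np.int64)
    for i in range(n_samples):
        total = mass[i].sum()
        if total <= 0:
            raise DataError(f"sample {i} has zero total latent mass")
        counts[i] = rng.multinomial(depths[i], mass[i] / total)
    cols = [f"otu_{k+1:04d}" for k in range(n_otus)]
    return pd.DataFrame(counts, index=lat.index, columns=cols)


def _plant_summaries(plant: pd.DataFrame, axes: pd.DataFrame) -> pd.DataFrame:
    from .plants import mesocosm_metrics

    return mesocosm_metrics(plant, axes)


def _zscore_cols(df: pd.DataFrame) -> pd.DataFrame:
    return (df - df.mean()) / df.std(ddof=1).replace(0, 1.0)


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, OtuTable, OtuTable, SyntheticTruth]:
    """Full dataset: plant biomass records, soil chemistry, prokaryote and
    fungal OTU tables, and the planted ground truth."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2025]))
    plant, axes = generate_plant_series(config, seed=config.seed)
    meso = _mesocosm_frame(config)
    summaries = _plant_summaries(plant, axes).set_index("mesocosm_id")
    summaries = summaries.loc[meso["mesocosm_id"]]

    plant_param_cols = [
        c for c in summaries.columns
        if c not in ("soil", "sowing_density")
    ]
    z_plant = _zscore_cols(summaries[plant_param_cols])

    # soil chemistry from standardized plant parameters + soil offset + noise
    pc = config.path_coefficients
    soil_ind = (meso["soil"] == "abandoned").to_numpy(dtype=float)
    chem = {}
    chem_z = {}
    for c in CHEM_VARS:
        betas = {p: b for (p, cc), b in pc.get("plant_chem", {}).items() if cc == c}
        signal = np.zeros(len(meso))
        for p, b in betas.items():
            signal += b * z_plant[p].to_numpy()
        resid_sd = config.noise_sd * np.sqrt(max(0.1, 1.0 - sum(b**2 for b in betas.values())))
        zc = signal + 0.3 * (soil_ind - soil_ind.mean()) + rng.normal(0, resid_sd, len(meso))
        chem_z[c] = zc
        mean, sd = CHEM_UNITS[c]
        chem[c] = mean + sd * zc
    chemistry = pd.DataFrame({"mesocosm_id": meso["mesocosm_id"], **chem})

    # microbial latent cluster masses with rank-matched coupled factors
    kp, kf = config.n_prok_clusters, config.n_fungal_clusters
    kmin = min(kp, kf)
    factors = {"prokaryote": np.zeros((len(meso), kp)),
               "fungal": np.zeros((len(meso), kf))}
    for si, soil in enumerate(SOILS):
        mask = (meso["soil"] == soil).to_numpy()
        n = mask.sum()
        rho = float(config.coupling_rho_per_soil[soil])
        z = rng.normal(size=(n, kmin))
        eps = rng.normal(size=(n, kmin))
        factors["prokaryote"][mask, :kmin] = z
        factors["fungal"][mask, :kmin] = rho * z + np.sqrt(1 - rho**2) * eps
        if kp > kmin:
            factors["prokaryote"][mask, kmin:] = rng.normal(size=(n, kp - kmin))
        if kf > kmin:
            factors["fungal"][mask, kmin:] = rng.normal(size=(n, kf - kmin))

    tables = {}
    truth_clusters = {}
    truth_specialists = {}
    for domain, n_otus, k in (
        ("prokaryote", config.n_prok_otus, kp),
        ("fungal", config.n_fungal_otus, kf),
    ):
        base_share = 0.65 ** np.arange(1, k + 1)
        b = np.log(base_share / base_share.sum())
        effect = np.zeros((len(meso), k))
        for (cvar, target), beta in pc.get("chem_microbe", {}).items():
            if target[0] == domain and 1 <= target[1] <= k:
                effect[:, target[1] - 1] += beta * chem_z[cvar]
        for (pvar, target), beta in pc.get("plant_microbe", {}).items():
            if target[0] == domain and 1 <= target[1] <= k:
                effect[:, target[1] - 1] += beta * z_plant[pvar].to_numpy()
        log_mass = b[None, :] + config.cluster_signal_sd * (factors[domain] + effect)
        latent = pd.DataFrame(
            np.exp(log_mass), index=meso["mesocosm_id"],
            columns=[f"cluster_{j+1}" for j in range(k)],
        )

        clusters = (np.arange(n_otus) % k) + 1  # round-robin, even split
        otu_base = rng.normal(0.0, config.otu_effect_sd, size=n_otus)
        n_spec = int(round(config.specialist_fraction * n_otus))
        spec_flags = np.zeros(n_otus, dtype=bool)
        spec_idx = rng.choice(n_otus, size=n_spec, replace=False)
        spec_flags[spec_idx] = True
        spec_sign = np.zeros(n_otus)
        spec_sign[spec_idx] = rng.choice([-1.0, 1.0], size=n_spec)
        half_lfc = 0.5 * np.log(config.specialist_fold_change)
        # +: enriched in natural soil; -: enriched in abandoned soil
        soil_sign = np.where(meso["soil"].to_numpy() == "natural", 1.0, -1.0)
        log_eff = otu_base[None, :] + soil_sign[:, None] * spec_sign[None, :] * half_lfc

        counts = generate_otu_counts(
            latent, clusters,
            depth_mean=config.depth_mean,
            depth_dispersion=config.depth_dispersion,
            nb_dispersion=config.nb_dispersion,
            otu_log_effects=log_eff,
            seed=int(rng.integers(2**31)),
        )
        prefix = "p" if domain == "prokaryote" else "f"
        counts.columns = [f"{prefix}_{c}" for c in counts.columns]
        habitat = pd.Series(meso["soil"].to_numpy(), index=counts.index)
        tables[domain] = OtuTable(counts, habitat, domain)
        truth_clusters[domain] = {o: int(c) for o, c in zip(counts.columns, clusters)}
        truth_specialists[domain] = {o: bool(s) for o, s in zip(counts.columns, spec_flags)}

    truth = SyntheticTruth(
        prok_clusters=truth_clusters["prokaryote"],
        fungal_clusters=truth_clusters["fungal"],
        prok_specialists=truth_specialists["prokaryote"],
        fungal_specialists=truth_specialists["fungal"],
        coupling_rho_per_soil=dict(config.coupling_rho_per_soil),
        path_coefficients=pc,
        axes=axes,
    )
    return plant, chemistry, tables["prokaryote"], tables["fungal"], truth
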