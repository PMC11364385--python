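"""Synthetic multi-tumor, two-platform single-cell panels with planted truth.

The generator emulates the statistical structure of a matched
primary-tumor/metastasis xenograft panel profiled with a deep plate-based
and a shallow droplet-based protocol:

* each cell carries a latent epithelial-mesenchymal axis ``t`` in [0, 1]
  drawn from a Beta law whose shape depends on the model's metastatic
  potential (low potential skews epithelial, high skews mesenchymal);
* an epithelial gene program scales with ``1 - t``, a mesenchymal program
  with ``t``, and intermediate-state markers follow a Gaussian bump peaked
  at ``t = 0.5``;
* a block of tissue genes carries a signed log2 effect in metastatic
  cells, and per-model copy-number segments multiply contiguous gene
  windows;
* model-specific lognormal gene offsets create inter-model heterogeneity
  (the batch structure that motivates the tumor-model covariate in DE);
* counts are negative-binomial around library-scaled relative means, and
  droplet cells suffer extra dropout.

Everything is driven by one integer seed; identical config + seed yields
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import ExpressionDataset, SurvivalCohort
from .errors import ConfigError

POTENTIAL_ORDER = ("low", "moderate", "high")


@dataclass(frozen=True)
class PlatformProfile:
    """Sequencing-depth profile of one protocol."""

    name: str
    library_size_mean: float
    library_size_sigma: float = 0.3  # sdlog of the lognormal library law
    dropout: float = 0.0  # extra per-entry zeroing probability

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout <= 1.0:
            raise ConfigError(f"dropout must be in [0,1], got {self.dropout}")
        if self.library_size_mean <= 0:
            raise ConfigError("library_size_mean must be positive")


DEFAULT_PLATFORMS = (
    PlatformProfile("plate", library_size_mean=5e4, dropout=0.0),
    PlatformProfile("droplet", library_size_mean=5e3, dropout=0.2),
)


@dataclass
class PanelConfig:
    """Study-design parameters of the simulated xenograft panel."""

    n_models: int = 10
    cells_per_model_per_tissue: int = 60  # primary-tumor cells per model
    #: metastatic cell yield relative to the primary yield, per potential
    #: class — metastases are rare in poorly metastatic models.
    met_cell_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.2, "moderate": 0.6, "high": 1.2}
    )
    n_genes: int = 1200
    n_epithelial: int = 60
    n_mesenchymal: int = 60
    n_intermediate: int = 30
    n_tissue_de: int = 40
    cnv_segment_genes: int = 120
    cnv_fold_change: float = 2.0
    shared_cnv: bool = True  # plant the same segment in both tissues
    beta_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"low": (2.0, 6.0), "moderate": (4.0, 4.0), "high": (6.0, 2.0)}
    )
    potential_counts: Mapping[str, int] = field(
        default_factory=lambda: {"low": 4, "moderate": 3, "high": 3}
    )
    tissue_log2fc: float = 1.0
    nb_dispersion: float = 10.0  # NB size theta; var = mu + mu^2/theta
    bump_sigma: float = 0.15
    program_base_mean: float = 3.0  # relative mean of program genes at full activation
    background_sdlog: float = 1.5  # sdlog of background baselines (wide, like real data)
    model_offset_sigma: float = 0.3  # sdlog of per-model per-gene lognormal offsets
    n_chromosomes: int = 6
    platforms: Sequence[PlatformProfile] = DEFAULT_PLATFORMS
    seed: int | None = None

    def validate(self) -> None:
        blocks = self.n_epithelial + self.n_mesenchymal + self.n_intermediate + self.n_tissue_de
        if blocks > self.n_genes:
            raise ConfigError("gene blocks exceed n_genes")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if sum(self.potential_counts.values()) != self.n_models:
            raise ConfigError("potential_counts must sum to n_models")
        if self.cnv_segment_genes > self.n_genes // self.n_chromosomes:
            raise ConfigError("cnv segment longer than one chromosome")
        for frac in self.met_cell_fraction.values():
            if frac < 0:
                raise ConfigError("met_cell_fraction must be non-negative")


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator, used by recovery tests."""

    latent_t: pd.Series  # per-cell EMP axis in [0,1]; 0 = epithelial
    de_genes: dict[str, float]  # gene -> signed log2 effect (metastasis vs primary)
    intermediate_markers: list[str]
    epithelial_genes: list[str]
    mesenchymal_genes: list[str]
    bump_sigma: float
    cnv_segments: dict[str, list[tuple[str, tuple[int, int], float]]]
    hazard_beta: float | None = None


def _model_names(config: PanelConfig) -> tuple[list[str], dict[str, str]]:
    names, potential = [], {}
    i = 0
    for pot in POTENTIAL_ORDER:
        for _ in range(config.potential_counts.get(pot, 0)):
            name = f"M{i:02d}"
            names.append(name)
            potential[name] = pot
            i += 1
    return names, potential


def _gene_table(config: PanelConfig) -> pd.DataFrame:
    symbols: list[str] = []
    blocks = [
        ("EPI", config.n_epithelial),
        ("MES", config.n_mesenchymal),
        ("INT", config.n_intermediate),
        ("TDE", config.n_tissue_de),
    ]
    for prefix, n in blocks:
        symbols += [f"{prefix}{i:04d}" for i in range(n)]
    n_bg = config.n_genes - len(symbols)
    symbols += [f"BG{i:04d}" for i in range(n_bg)]
    per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))
    chroms = [str(1 + i // per_chrom) for i in range(config.n_genes)]
    starts = [1_000_000 * (1 + i % per_chrom) for i in range(config.n_genes)]
    return pd.DataFrame({"chromosome": chroms, "start": starts}, index=pd.Index(symbols, name="symbol"))


def simulate_panel(config: PanelConfig) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Render the panel on all configured platforms from one shared truth."""
    config.validate()
    if config.seed is None:
        raise ConfigError("simulate_panel requires an explicit seed")
    rng = np.random.default_rng(config.seed)

    models, potential_of = _model_names(config)
    gene_meta = _gene_table(config)
    genes = gene_meta.index
    G = config.n_genes

    n_epi, n_mes = config.n_epithelial, config.n_mesenchymal
    n_int, n_tde = config.n_intermediate, config.n_tissue_de
    epi_idx = np.arange(0, n_epi)
    mes_idx = np.arange(n_epi, n_epi + n_mes)
    int_idx = np.arange(n_epi + n_mes, n_epi + n_mes + n_int)
    tde_idx = np.arange(n_epi + n_mes + n_int, n_epi + n_mes + n_int + n_tde)

    # Per-gene relative baselines: background ~1, program/DE genes stronger
    # so the planted structure is detectable at droplet depth.
    base = rng.lognormal(mean=0.0, sigma=config.background_sdlog, size=G)
    for idx in (epi_idx, mes_idx, int_idx, tde_idx):
        base[idx] = rng.lognormal(mean=np.log(config.program_base_mean), sigma=0.3, size=idx.size)

    # Signed tissue effects: alternate up/down in metastatic cells.
    effects = np.where(np.arange(n_tde) % 2 == 0, 1.0, -1.0) * config.tissue_log2fc
    de_genes = {genes[j]: float(e) for j, e in zip(tde_idx, effects)}

    # Per-model lognormal gene offsets (inter-model heterogeneity).
    offsets = {
        m: rng.lognormal(mean=0.0, sigma=config.model_offset_sigma, size=G) for m in models
    }

    # Per-model CNV segments on pure-background chromosomes (>= chrom 2).
    chrom_labels = gene_meta["chromosome"].to_numpy()
    cnv_segments: dict[str, list[tuple[str, tuple[int, int], float]]] = {}
    eligible_chroms = sorted(set(chrom_labels) - {chrom_labels[0]}, key=int)
    for m in models:
        chrom = eligible_chroms[int(rng.integers(len(eligible_chroms)))]
        positions = np.flatnonzero(chrom_labels == chrom)
        max_start = positions.size - config.cnv_segment_genes
        start = int(rng.integers(max_start + 1))
        lo, hi = int(positions[start]), int(positions[start + config.cnv_segment_genes - 1]) + 1
        fold = config.cnv_fold_change if rng.random() < 0.5 else 1.0 / config.cnv_fold_change
        cnv_segments[m] = [(chrom, (lo, hi), float(fold))]

    # Draw each model's latent axis once per (model, tissue, cell slot);
    # platforms re-render the same latent draw (shared truth).
    n_primary = config.cells_per_model_per_tissue
    latent: dict[tuple[str, str], np.ndarray] = {}
    for m in models:
        a, b = config.beta_params[potential_of[m]]
        n_met = int(round(n_primary * config.met_cell_fraction[potential_of[m]]))
        latent[(m, "primary")] = rng.beta(a, b, size=n_primary)
        latent[(m, "metastasis")] = rng.beta(a, b, size=max(n_met, 0))

    cell_rows = []
    t_values = []
    mu_rows = []
    for platform in config.platforms:
        for m in models:
            for tissue in ("primary", "metastasis"):
                t_vec = latent[(m, tissue)]
                if t_vec.size == 0:
                    continue
                factor = np.ones((t_vec.size, G))
                factor[:, epi_idx] = (1.0 - t_vec)[:, None]
                factor[:, mes_idx] = t_vec[:, None]
                factor[:, int_idx] = np.exp(
                    -((t_vec - 0.5) ** 2) / (2.0 * config.bump_sigma**2)
                )[:, None]
                if tissue == "metastasis":
                    factor[:, tde_idx] *= 2.0 ** effects[None, :]
                mu = base[None, :] * offsets[m][None, :] * factor
                for chrom, (lo, hi), fold in cnv_segments[m]:
                    if config.shared_cnv or tissue == "metastasis":
                        mu[:, lo:hi] *= fold
                mu_rows.append(mu)
                for k, t in enumerate(t_vec):
                    cell_rows.append(
                        {
                            "cell_id": f"{platform.name}_{m}_{tissue}_{k:04d}",
                            "tumor_model": m,
                            "tissue": tissue,
                            "platform": platform.name,
                            "metastatic_potential": potential_of[m],
                        }
                    )
                    t_values.append(float(t))

    mu_all = np.vstack(mu_rows)
    cell_meta = pd.DataFrame(cell_rows).set_index("cell_id")
    n_cells = len(cell_meta)

    # Library sizes and NB sampling (gamma-Poisson mixture).
    libs = np.empty(n_cells)
    for platform in config.platforms:
        mask = (cell_meta["platform"] == platform.name).to_numpy()
        libs[mask] = rng.lognormal(
            mean=np.log(platform.library_size_mean), sigma=platform.library_size_sigma, size=mask.sum()
        )
    mu_scaled = mu_all * (libs / mu_all.sum(axis=1))[:, None]
    theta = config.nb_dispersion
    counts = rng.poisson(rng.gamma(shape=theta, scale=mu_scaled / theta))

    for platform in config.platforms:
        if platform.dropout > 0:
            mask = (cell_meta["platform"] == platform.name).to_numpy()
            keep = rng.random(size=(int(mask.sum()), G)) >= platform.dropout
            counts[mask] = counts[mask] * keep

    # Guard against an (astronomically unlikely) all-zero cell.
    empty = counts.sum(axis=1) == 0
    if empty.any():
        counts[np.flatnonzero(empty), 0] = 1

    dataset = ExpressionDataset(counts=counts, cell_meta=cell_meta, gene_meta=gene_meta)
    truth = SyntheticTruth(
        latent_t=pd.Series(t_values, index=cell_meta.index, name="latent_t"),
        de_genes=de_genes,
        intermediate_markers=[genes[j] for j in int_idx],
        epithelial_genes=[genes[j] for j in epi_idx],
        mesenchymal_genes=[genes[j] for j in mes_idx],
        bump_sigma=config.bump_sigma,
        cnv_segments=cnv_segments,
    )
    return dataset, truth


def simulate_survival(
    n_patients: int,
    hazard_beta: float,
    signature_genes: Sequence[str],
    censor_rate: float = 0.2,
    seed: int | None = None,
    baseline_rate: float = 0.02,
    noise_sigma: float = 1.0,
    censor_horizon: float = 120.0,
    n_background_genes: int = 20,
    subtype_probs: Mapping[str, float] | None = None,
) -> tuple[SurvivalCohort, SyntheticTruth]:
    """Cohort whose hazard is log-linear in a latent signature score.

    Score ``s ~ N(0,1)`` drives the expression of ``signature_genes``
    (plus Gaussian noise) and an exponential event time with rate
    ``baseline_rate * exp(hazard_beta * s)``.  With probability
    ``censor_rate`` a patient additionally has a Uniform(0, horizon)
    censoring time; subtype labels are multinomial.
    """
    if n_patients < 2:
        raise ConfigError("need at least 2 patients")
    if censor_rate < 0 or censor_rate > 1:
        raise ConfigError("censor_rate must be in [0,1]")
    if seed is None:
        raise ConfigError("simulate_survival requires an explicit seed")
    rng = np.random.default_rng(seed)
    probs = subtype_probs or {"LumA": 0.4, "LumB": 0.2, "Basal": 0.3, "Her2": 0.1}
    names = list(probs)
    p = np.asarray([probs[k] for k in names], dtype=float)
    p = p / p.sum()

    s = rng.standard_normal(n_patients)
    expr = {
        g: s + noise_sigma * rng.standard_normal(n_patients) for g in signature_genes
    }
    for j in range(n_background_genes):
        expr[f"NULL{j:03d}"] = rng.standard_normal(n_patients)
    event_time = rng.exponential(1.0 / (baseline_rate * np.exp(hazard_beta * s)))
    has_censor = rng.random(n_patients) < censor_rate
    censor_time = np.where(has_censor, rng.uniform(0, censor_horizon, n_patients), np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    subtype = rng.choice(names, size=n_patients, p=p)

    cohort = SurvivalCohort(
        time=time, event=event, subtype=subtype, expression=pd.DataFrame(expr)
    )
    truth = SyntheticTruth(
        latent_t=pd.Series(s, name="score"),
        de_genes={},
        intermediate_markers=[],
        epithelial_genes=[],
        mesenchymal_genes=[],
        bump_sigma=float("nan"),
        cnv_segments={},
        hazard_beta=hazard_beta,
    )
    return cohort, truth


def simulate_foci(
    n_foci: int,
    size_distribution: Sequence[tuple[int, float]],
    seed: int | None = None,
    tissue_area: float = 100.0,
    area_per_cell: float = 1e-4,
) -> tuple[list[tuple[int, float]], float]:
    """Draw metastatic focus sizes from a discrete mixture.

    ``size_distribution`` is a sequence of ``(cell_count, probability)``
    pairs.  Focus area scales linearly with cell count.  Returns
    ``(foci, tissue_area)`` with foci as ``(cell_count, area_mm2)`` pairs.
    """
    if seed is None:
        raise ConfigError("simulate_foci requires an explicit seed")
    sizes = np.asarray([s for s, _ in size_distribution], dtype=int)
    probs = np.asarray([p for _, p in size_distribution], dtype=float)
    if (sizes < 1).any():
        raise ConfigError("focus sizes must be positive")
    if (probs < 0).any() or probs.sum() <= 0:
        raise ConfigError("mixture probabilities must be non-negative and sum > 0")
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    draws = rng.choice(sizes, size=n_foci, p=probs)
    foci = [(int(c), float(c * area_per_cell)) for c in draws]
    return foci, tissue_area
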