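"""Synthetic multi-tissue expression data with planted disease genes.

The generator emulates the structure the integrative analysis assumes:
strictly positive expression, tissue-selective baselines, genotype-
dependent case perturbations of graded severity, and a set of planted
"disease" genes whose *inter-tissue* differential signal exceeds that
of background genes.  Expression is log-normal:

    value(g, s) = exp( μ_g + τ_{g, tissue(s)} + δ_{g, genotype(s)} + ε_{g,s} )

with μ_g ~ N(baseline_log_mean, baseline_log_sd²) the gene baseline,
τ_{g,t} ~ N(0, tissue_effect_sd²) a per-gene per-tissue offset,
ε ~ N(0, noise_sd²) sample noise.  Each planted gene additionally gets

* a fixed +disease_intertissue_effect added to τ in the designated
  disease tissue (default: the first tissue, emulating a tissue-
  selective disease signature such as a striatal one), creating an
  inter-tissue fold change in both conditions, and
* δ = disease_case_effect · severity · m_g in case samples, a within-
  tissue case perturbation.  Severity grows linearly with genotype
  index (mimicking a polyQ allelic series) and m_g ~ |N(0,1)| is a
  per-gene half-normal responsiveness: some disease genes respond
  strongly during disease progression, others hardly at all — the hard
  cases that motivate looking at inter-tissue signal in the first
  place.

Labels mark the planted genes +1 and an equal-sized random background
subset -1; the remaining genes stay unlabeled, so ranking always
operates on a superset of the labeled genes.  All randomness flows from
one integer seed through numpy's PCG64 generator, so outputs are
bit-reproducible per seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, LabelSet
from .errors import ConfigurationError


@dataclass(frozen=True)
class SimulationConfig:
    """Shape and effect sizes of one simulated dataset.

    Defaults mirror a three-tissue, six-genotype design with 8
    replicates per tissue-genotype group (144 samples), one normal
    genotype and five case genotypes of increasing severity.
    """

    n_genes: int = 2000
    n_disease: int = 89
    tissues: tuple[str, ...] = ("Str", "Cor", "Liv")
    genotypes: tuple[str, ...] = ("Q20", "Q80", "Q92", "Q111", "Q140", "Q175")
    normal_genotype: str = "Q20"
    disease_tissue: str | None = None  # None -> first tissue
    replicates_per_group: int = 8
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.0
    tissue_effect_sd: float = 0.5
    disease_intertissue_effect: float = 1.5
    disease_case_effect: float = 0.5
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_disease > self.n_genes:
            raise ConfigurationError("n_disease must be <= n_genes")
        if 2 * self.n_disease > self.n_genes:
            raise ConfigurationError(
                "need n_genes >= 2*n_disease to draw an equal-sized negative set"
            )
        for name in ("baseline_log_sd", "tissue_effect_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.disease_intertissue_effect < 0 or self.disease_case_effect < 0:
            raise ConfigurationError("effect sizes must be >= 0")
        if self.normal_genotype not in self.genotypes:
            raise ConfigurationError("normal_genotype must be one of genotypes")
        if self.disease_tissue is not None and self.disease_tissue not in self.tissues:
            raise ConfigurationError("disease_tissue must be one of tissues")
        if len(set(self.tissues)) != len(self.tissues) or len(set(self.genotypes)) != len(self.genotypes):
            raise ConfigurationError("tissue and genotype names must be unique")
        if self.replicates_per_group < 1 or self.n_genes < 1:
            raise ConfigurationError("n_genes and replicates_per_group must be >= 1")

    @property
    def n_samples(self) -> int:
        return len(self.tissues) * len(self.genotypes) * self.replicates_per_group


@dataclass
class SimulationTruth:
    """Ground truth of one simulation, for tests and audits."""

    planted_genes: list[str]
    negative_genes: list[str]
    disease_tissue: str            # tissue carrying the planted inter-tissue offset
    case_response: pd.Series       # planted gene -> half-normal responsiveness m_g
    mu: pd.Series                  # per-gene log baseline
    tau: pd.DataFrame              # genes x tissues log offsets (incl. planted shift)
    delta: pd.DataFrame            # genes x genotypes log case effects


def simulate(config: SimulationConfig) -> tuple[ExpressionMatrix, LabelSet, SimulationTruth]:
    """Draw one dataset; same config (incl. seed) gives bit-identical output."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    G, T = config.n_genes, len(config.tissues)
    width = max(5, len(str(config.n_genes)))
    genes = [f"g{i:0{width}d}" for i in range(1, G + 1)]

    sample_rows = []
    for tissue in config.tissues:
        for geno in config.genotypes:
            cond = "normal" if geno == config.normal_genotype else "case"
            for r in range(1, config.replicates_per_group + 1):
                sample_rows.append((f"{tissue}_{geno}_s{r}", tissue, geno, cond))
    meta = pd.DataFrame(
        sample_rows, columns=["sample_id", "tissue", "genotype", "condition"]
    ).set_index("sample_id")

    mu = rng.normal(config.baseline_log_mean, config.baseline_log_sd, G)
    tau = rng.normal(0.0, config.tissue_effect_sd, (G, T))

    planted_idx = np.sort(rng.choice(G, size=config.n_disease, replace=False))
    disease_tissue = config.disease_tissue or config.tissues[0]
    tau[planted_idx, config.tissues.index(disease_tissue)] += config.disease_intertissue_effect

    case_response = np.abs(rng.normal(0.0, 1.0, size=config.n_disease))
    case_genos = [g for g in config.genotypes if g != config.normal_genotype]
    delta = np.zeros((G, len(config.genotypes)))
    for j, geno in enumerate(config.genotypes):
        if geno == config.normal_genotype:
            continue
        severity = (case_genos.index(geno) + 1) / len(case_genos)
        delta[planted_idx, j] = config.disease_case_effect * severity * case_response

    noise = rng.normal(0.0, config.noise_sd, (G, len(meta)))
    tissue_of = meta["tissue"].map({t: i for i, t in enumerate(config.tissues)}).to_numpy()
    geno_of = meta["genotype"].map({g: i for i, g in enumerate(config.genotypes)}).to_numpy()
    log_expr = mu[:, None] + tau[:, tissue_of] + delta[:, geno_of] + noise
    values = pd.DataFrame(np.exp(log_expr), index=genes, columns=meta.index)

    planted = [genes[i] for i in planted_idx]
    background = np.setdiff1d(np.arange(G), planted_idx)
    negative_idx = np.sort(rng.choice(background, size=config.n_disease, replace=False))
    negatives = [genes[i] for i in negative_idx]
    labels = LabelSet(pd.Series(
        [1] * len(planted) + [-1] * len(negatives), index=planted + negatives, dtype=int
    ))

    truth = SimulationTruth(
        planted_genes=planted,
        negative_genes=negatives,
        disease_tissue=disease_tissue,
        case_response=pd.Series(case_response, index=planted),
        mu=pd.Series(mu, index=genes),
        tau=pd.DataFrame(tau, index=genes, columns=list(config.tissues)),
        delta=pd.DataFrame(delta, index=genes, columns=list(config.genotypes)),
    )
    return ExpressionMatrix(values, meta), labels, truth


def default_study_shape(seed: int, n_genes: int = 2000, n_disease: int = 89) -> SimulationConfig:
    """A config with the canonical 3 tissues × 6 genotypes × 8 replicates
    = 144 sample layout and a desk-scale gene count."""
    return SimulationConfig(n_genes=n_genes, n_disease=n_disease, seed=seed)
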