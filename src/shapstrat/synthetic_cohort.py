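"""Synthetic immunotherapy cohorts with four planted immune subclasses.

The generator emulates the statistical structure the stratification pipeline
assumes in a bulk-RNA immunotherapy cohort: a log2-TPM expression matrix with
background genes plus three expression modules (T-cell activation,
immunosuppression, TGF-beta signalling) whose means shift per planted
subclass; RECIST response labels drawn from per-subclass responder
probabilities; binary mutation indicators (TP53 / FGFR3 / RB1 patterned on
the subclass profiles); and exponential overall-survival times with
independent censoring. Planted truth travels with the cohort so recovery can
be scored with the adjusted Rand index.

Default subclass proportions (0.34/0.19/0.25/0.22) and responder
probabilities (0.00/0.23/0.77/0.92) echo the qualitative profile of the four
patient subclasses the pipeline is designed to expose; they are generator
defaults, not claims of equivalence to any real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_io import ClinicalTable, ExpressionMatrix, MutationTable

MODULE_NAMES = ("t_activation", "suppression", "tgf_beta")
MUTATION_GENES = ("TP53", "FGFR3", "RB1")

# marker symbols placed at the head of each module so downstream panel
# defaults resolve out of the box
T_ACTIVATION_MARKERS = ("CXCL9", "CXCL10", "CXCL13", "GZMB")
TGF_MARKERS = ("TGFB1",)

DEFAULT_SUBCLASS_PROPS = (0.34, 0.19, 0.25, 0.22)
DEFAULT_RESPONSE_PROBS = (0.00, 0.23, 0.77, 0.92)
# rows = subclass 1..4, cols = (t_activation, suppression, tgf_beta);
# entries multiply the scalar `effect`
DEFAULT_MODULE_PATTERN = (
    (0.0, 0.0, 1.0),
    (1.0, 1.0, 1.0),
    (0.0, 0.0, 0.0),
    (1.0, 0.0, 0.0),
)
# rows = subclass, cols = (TP53, FGFR3, RB1)
DEFAULT_MUTATION_PROBS = (
    (0.15, 0.55, 0.08),
    (0.65, 0.10, 0.50),
    (0.15, 0.55, 0.08),
    (0.65, 0.10, 0.08),
)
# exponential OS rates, log(2)/median with medians ~ (5.7, 7.9, 21.2, 40) months
DEFAULT_HAZARDS = (0.1216, 0.0877, 0.0327, 0.0173)
DEFAULT_PDL1_HIGH_PROBS = (0.17, 0.52, 0.17, 0.66)
# rows = subclass, cols = (desert, excluded, inflamed)
DEFAULT_PHENOTYPE_PROBS = (
    (0.45, 0.45, 0.10),
    (0.16, 0.44, 0.40),
    (0.36, 0.50, 0.14),
    (0.06, 0.45, 0.49),
)
DEFAULT_TMB_MEANS = (8.7, 9.3, 12.8, 12.7)


@dataclass
class CohortTruth:
    """Planted ground truth and the parameters that generated it."""

    subclass: np.ndarray
    subclass_props: np.ndarray
    response_probs: np.ndarray
    module_effects: np.ndarray  # 4 x 3 log2 mean shifts
    mutation_probs: np.ndarray  # 4 x len(MUTATION_GENES)
    hazard: np.ndarray
    seed: int
    module_genes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.subclass = np.asarray(self.subclass, dtype=int)
        self.subclass_props = np.asarray(self.subclass_props, dtype=float)
        self.response_probs = np.asarray(self.response_probs, dtype=float)
        self.module_effects = np.asarray(self.module_effects, dtype=float)
        self.mutation_probs = np.asarray(self.mutation_probs, dtype=float)
        self.hazard = np.asarray(self.hazard, dtype=float)
        if not np.isclose(self.subclass_props.sum(), 1.0):
            raise ValueError("subclass_props must sum to 1")
        if np.any((self.response_probs < 0) | (self.response_probs > 1)):
            raise ValueError("response_probs must lie in [0, 1]")
        if np.any(self.hazard <= 0):
            raise ValueError("hazards must be positive")


@dataclass
class SyntheticCohort:
    expr: ExpressionMatrix
    clinical: ClinicalTable
    mutations: MutationTable
    truth: CohortTruth

    def __post_init__(self) -> None:
        ids = self.expr.sample_ids
        if self.clinical.sample_ids != ids:
            raise ValueError("clinical sample ids not aligned with expression")
        if len(self.truth.subclass) != len(ids):
            raise ValueError("truth not aligned with expression samples")

    def write_dir(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.expr.write_csv(out / "expr.csv")
        self.clinical.write_csv(out / "clinical.csv")
        self.mutations.write_csv(out / "mutations.csv")
        pd.DataFrame(
            {"sample_id": self.expr.sample_ids, "subclass": self.truth.subclass}
        ).to_csv(out / "truth.csv", index=False)


def _module_gene_names(genes_per_module: int) -> dict[str, list[str]]:
    names: dict[str, list[str]] = {}
    for module in MODULE_NAMES:
        markers: tuple[str, ...] = ()
        if module == "t_activation":
            markers = T_ACTIVATION_MARKERS
        elif module == "tgf_beta":
            markers = TGF_MARKERS
        prefix = {"t_activation": "TACT", "suppression": "SUPP", "tgf_beta": "TGFM"}[module]
        filler = [f"{prefix}{i:02d}" for i in range(1, genes_per_module - len(markers) + 1)]
        names[module] = list(markers) + filler
    return names


def generate_cohort(
    n: int = 300,
    g_background: int = 150,
    genes_per_module: int = 15,
    effect: float = 1.5,
    noise_sd: float = 1.0,
    censor_rate: float = 0.3,
    subclass_props=DEFAULT_SUBCLASS_PROPS,
    response_probs=DEFAULT_RESPONSE_PROBS,
    module_pattern=DEFAULT_MODULE_PATTERN,
    mutation_probs=DEFAULT_MUTATION_PROBS,
    hazards=DEFAULT_HAZARDS,
    cr_within_responders: float = 0.3,
    sd_within_nonresponders: float = 0.25,
    seed: int = 0,
) -> SyntheticCohort:
    """Draw a fully reproducible synthetic cohort.

    Parameters
    ----------
    n
        Cohort size (>= 40 so every planted subclass is populated).
    g_background, genes_per_module
        Background gene count and size of each of the 3 planted modules.
    effect
        log2 mean shift applied where ``module_pattern`` is 1.
    noise_sd
        Per-gene Gaussian noise standard deviation on the log2 scale.
    censor_rate
        Probability a sample's survival time is administratively censored;
        censored observation times are Uniform(0, T). 0 disables censoring.
    """
    if n < 40:
        raise ValueError("need n >= 40 to populate all subclasses")
    if genes_per_module < max(len(T_ACTIVATION_MARKERS), 1):
        raise ValueError("genes_per_module too small for marker symbols")
    if genes_per_module * len(MODULE_NAMES) > genes_per_module * 3 + g_background:
        raise ValueError("module genes exceed the total gene budget")
    if not (0.0 <= censor_rate <= 1.0):
        raise ValueError("censor_rate must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    props = np.asarray(subclass_props, dtype=float)
    module_effects = np.asarray(module_pattern, dtype=float) * effect

    subclass = rng.choice(np.arange(1, 5), size=n, p=props)
    sample_ids = [f"P{i:04d}" for i in range(1, n + 1)]

    module_genes = _module_gene_names(genes_per_module)
    background_genes = [f"BG{i:04d}" for i in range(1, g_background + 1)]
    gene_ids = background_genes + [g for m in MODULE_NAMES for g in module_genes[m]]

    g_total = len(gene_ids)
    baseline = rng.uniform(2.0, 8.0, size=g_total)
    values = baseline[:, None] + rng.normal(0.0, noise_sd, size=(g_total, n))
    for m_idx, module in enumerate(MODULE_NAMES):
        rows = [gene_ids.index(g) for g in module_genes[module]]
        shift = module_effects[subclass - 1, m_idx]  # per sample
        values[np.ix_(rows, range(n))] += shift[None, :]
    values = np.clip(values, 0.0, None)  # log2(TPM+1) is non-negative
    expr = ExpressionMatrix(values, gene_ids, sample_ids)

    resp_p = np.asarray(response_probs, dtype=float)[subclass - 1]
    responder = rng.random(n) < resp_p
    response = np.empty(n, dtype=object)
    u = rng.random(n)
    response[responder] = np.where(u[responder] < cr_within_responders, "CR", "PR")
    response[~responder] = np.where(u[~responder] < sd_within_nonresponders, "SD", "PD")

    hazard = np.asarray(hazards, dtype=float)[subclass - 1]
    event_time = rng.exponential(1.0 / hazard)
    censored = rng.random(n) < censor_rate
    os_months = np.where(censored, rng.uniform(0.0, event_time), event_time)
    os_event = (~censored).astype(int)

    pdl1 = np.where(
        rng.random(n) < np.asarray(DEFAULT_PDL1_HIGH_PROBS)[subclass - 1], "high", "low"
    )
    pheno_probs = np.asarray(DEFAULT_PHENOTYPE_PROBS, dtype=float)
    phenotype = np.array(
        [rng.choice(["desert", "excluded", "inflamed"], p=pheno_probs[s - 1]) for s in subclass]
    )
    tmb = rng.gamma(shape=4.0, scale=np.asarray(DEFAULT_TMB_MEANS)[subclass - 1] / 4.0)

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "response": response,
                "os_months": os_months,
                "os_event": os_event,
                "pdl1_level": pdl1,
                "immune_phenotype": phenotype,
                "tmb": tmb,
            }
        )
    )

    mut_probs = np.asarray(mutation_probs, dtype=float)
    rows = []
    for j, gene in enumerate(MUTATION_GENES):
        mutated = (rng.random(n) < mut_probs[subclass - 1, j]).astype(int)
        rows.append(pd.DataFrame({"sample_id": sample_ids, "gene": gene, "mutated": mutated}))
    mutations = MutationTable(pd.concat(rows, ignore_index=True))

    truth = CohortTruth(
        subclass=subclass,
        subclass_props=props,
        response_probs=np.asarray(response_probs, dtype=float),
        module_effects=module_effects,
        mutation_probs=mut_probs,
        hazard=np.asarray(hazards, dtype=float),
        seed=seed,
        module_genes=module_genes,
    )
    return SyntheticCohort(expr, clinical, mutations, truth)


def nb_counts(
    expr: ExpressionMatrix, dispersion: float = 0.1, lib_size: float = 2e6, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Optional negative-binomial count layer over a log2 expression matrix.

    Returns (counts, gene lengths in bases); intended for exercising the
    TPM normalisation path, not for realistic RNA-seq noise.
    """
    rng = np.random.default_rng(seed)
    lengths = rng.uniform(500, 5000, size=expr.n_genes)
    tpm_like = 2.0**expr.values - 1.0
    frac = tpm_like / tpm_like.sum(axis=0, keepdims=True)
    mean = frac * lengths[:, None]
    mean = mean / mean.sum(axis=0, keepdims=True) * lib_size
    r = 1.0 / dispersion
    p = r / (r + np.maximum(mean, 1e-12))
    counts = rng.negative_binomial(r, p)
    return counts.astype(int), lengths


def truth_ari(assign, truth: CohortTruth) -> float:
    """Adjusted Rand index between recovered (flattened) labels and truth."""
    from sklearn.metrics import adjusted_rand_score

    if len(assign.sample_ids) != len(truth.subclass):
        raise ValueError("assignment and truth have different sample counts")
    return float(adjusted_rand_score(truth.subclass, assign.flat_labels))
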