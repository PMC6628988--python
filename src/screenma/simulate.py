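"""Synthetic pooled-screen generator with ground truth.

Emulates the statistical structure the MA-plot scorer assumes: a library
of ~12,000 guides (1378 target genes + 56 negative-control genes, 8
guides each), log-normal spread of true guide abundances, overdispersed
negative-binomial counts whose dispersion — and hence the spread of the
log ratio M — decays with abundance A, two biological replicates each
pairing an induced sample with its own pre-induction draw, and an
optional set of spiked "bypass" genes whose effective guides are enriched
in the induced samples.  Guide-efficiency heterogeneity (only a fraction
of a bypass gene's guides respond) stresses the >=3-guides gene rule the
way real screens do.

Counts are drawn gamma-Poisson: lambda ~ Gamma(1/phi, mu*phi), count ~
Poisson(lambda), giving mean mu and variance mu + phi*mu^2 with
phi = dispersion_alpha0 * exp(-dispersion_decay * log10(mu)).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .library import ReadBatch, ScreenCountTable, SgRNARecord

__all__ = [
    "SyntheticScreenConfig",
    "SyntheticScreenTruth",
    "simulate_screen",
    "simulate_reads",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticScreenConfig:
    """Study-scale defaults: 1378 + 56 genes x 8 guides ~ 11,500 sgRNAs."""

    n_genes: int = 1378
    sgrnas_per_gene: int = 8
    n_control_genes: int = 56
    controls_sgrnas_per_gene: int = 8
    n_replicates: int = 2
    depth: float = 500.0          # expected reads per sgRNA per sample
    baseline_log10_sd: float = 0.4
    dispersion_alpha0: float = 0.15
    dispersion_decay: float = 0.5  # per log10-mean unit
    n_bypass_genes: int = 0
    bypass_log10_enrichment: float = 0.6
    efficiency_p: float = 0.75
    spacer_length: int = 19
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.sgrnas_per_gene, self.n_control_genes,
               self.controls_sgrnas_per_gene, self.n_replicates) < 1:
            raise ValueError("library geometry parameters must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.baseline_log10_sd < 0 or self.dispersion_alpha0 < 0:
            raise ValueError("spread/dispersion parameters must be non-negative")
        if not (0 <= self.efficiency_p <= 1):
            raise ValueError("efficiency_p must be in [0, 1]")
        if not (0 <= self.n_bypass_genes <= self.n_genes):
            raise ValueError("n_bypass_genes must be in [0, n_genes]")


@dataclass
class SyntheticScreenTruth:
    """Ground truth for every stage's tests."""

    genes: pd.DataFrame = field(repr=False)   # gene_id, is_control, is_bypass, enrichment
    sgrnas: pd.DataFrame = field(repr=False)  # sgrna_id, gene_id, baseline, effective, expected_m
    config: SyntheticScreenConfig = None

    @property
    def bypass_genes(self) -> list[str]:
        return sorted(self.genes.loc[self.genes["is_bypass"], "gene_id"])


def _make_library(config: SyntheticScreenConfig, rng: np.random.Generator) -> list[SgRNARecord]:
    records = []
    seen: set[str] = set()

    def new_spacer() -> str:
        while True:
            sp = "".join(rng.choice(_BASES, size=config.spacer_length))
            if sp not in seen:
                seen.add(sp)
                return sp

    for g in range(config.n_genes):
        gene = f"GENE{g + 1:04d}"
        for k in range(config.sgrnas_per_gene):
            records.append(SgRNARecord(f"{gene}_sg{k + 1}", new_spacer(), gene, False))
    for g in range(config.n_control_genes):
        gene = f"NEG{g + 1:03d}"
        for k in range(config.controls_sgrnas_per_gene):
            records.append(SgRNARecord(f"{gene}_sg{k + 1}", new_spacer(), gene, True))
    return records


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Gamma-Poisson negative binomial; phi -> 0 degenerates to Poisson."""
    lam = np.where(
        phi > 1e-12,
        rng.gamma(shape=1.0 / np.maximum(phi, 1e-12), scale=mu * np.maximum(phi, 1e-12)),
        mu,
    )
    return rng.poisson(lam)


def simulate_screen(
    config: SyntheticScreenConfig,
) -> tuple[ScreenCountTable, SyntheticScreenTruth, list[SgRNARecord]]:
    """Generate counts for n_replicates (pre-induction, induced) sample pairs.

    Returns the count table, the ground truth, and the generated library.
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    library = _make_library(config, rng)
    sgrna_ids = [r.sgrna_id for r in library]
    gene_ids = np.array([r.gene_id for r in library])
    is_ctrl_sgrna = np.array([r.is_negative_control for r in library])
    n = len(library)

    target_genes = [f"GENE{g + 1:04d}" for g in range(config.n_genes)]
    bypass = set(
        rng.choice(np.array(target_genes), size=config.n_bypass_genes, replace=False)
    )
    # baseline relative abundances, log-normal with the given log10 spread
    baseline = rng.lognormal(
        mean=0.0, sigma=config.baseline_log10_sd * np.log(10), size=n
    )
    mu0 = config.depth * baseline / baseline.mean()

    is_bypass_sgrna = np.isin(gene_ids, list(bypass))
    effective = is_bypass_sgrna & (rng.random(n) < config.efficiency_p)
    fold = np.where(effective, 10.0 ** config.bypass_log10_enrichment, 1.0)
    mu_induced = mu0 * fold

    def phi_of(mu: np.ndarray) -> np.ndarray:
        return config.dispersion_alpha0 * np.exp(
            -config.dispersion_decay * np.log10(np.maximum(mu, 1e-9))
        )

    columns: dict[str, np.ndarray] = {}
    sample_rows = []
    for r in range(1, config.n_replicates + 1):
        pre, ind = f"pre_r{r}", f"ind_r{r}"
        columns[pre] = _nb_draw(rng, mu0, phi_of(mu0))
        columns[ind] = _nb_draw(rng, mu_induced, phi_of(mu_induced))
        sample_rows.append((pre, "pre_induction", f"r{r}", None))
        sample_rows.append((ind, "induced", f"r{r}", pre))

    counts = pd.DataFrame(columns, index=pd.Index(sgrna_ids, name="sgrna_id"))
    samples = pd.DataFrame(
        sample_rows,
        columns=["sample_id", "condition", "replicate_id", "paired_control_id"],
    )
    table = ScreenCountTable(counts=counts, samples=samples)

    all_genes = target_genes + [f"NEG{g + 1:03d}" for g in range(config.n_control_genes)]
    genes_df = pd.DataFrame(
        {
            "gene_id": all_genes,
            "is_control": [g.startswith("NEG") for g in all_genes],
            "is_bypass": [g in bypass for g in all_genes],
            "enrichment": [
                config.bypass_log10_enrichment if g in bypass else 0.0
                for g in all_genes
            ],
        }
    )
    sgrnas_df = pd.DataFrame(
        {
            "sgrna_id": sgrna_ids,
            "gene_id": gene_ids,
            "is_control": is_ctrl_sgrna,
            "baseline": baseline,
            "effective": effective,
            "expected_m": np.where(effective, config.bypass_log10_enrichment, 0.0),
        }
    )
    truth = SyntheticScreenTruth(genes=genes_df, sgrnas=sgrnas_df, config=config)
    return table, truth, library


def _mutate_one_base(spacer: str, rng: np.random.Generator) -> str:
    pos = int(rng.integers(len(spacer)))
    old = spacer[pos]
    new = str(rng.choice(_BASES[_BASES != old]))
    return spacer[:pos] + new + spacer[pos + 1 :]


def simulate_reads(
    counts: ScreenCountTable,
    library,
    flank5: str,
    flank3: str,
    error_rate: float = 0.0,
    seed: int = 0,
    pad_length: int = 4,
) -> dict[str, ReadBatch]:
    """Emit pad+flank5+spacer+flank3+pad reads, one batch per sample.

    Each sgRNA contributes exactly its count's reads; with probability
    ``error_rate`` a read carries one random substitution inside the
    spacer (so at error_rate=1 no read matches exactly).  Reads are
    shuffled deterministically by ``seed``.
    """
    if not (0 <= error_rate <= 1):
        raise ValueError("error_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    spacer_of = {r.sgrna_id: r.spacer for r in library}
    batches: dict[str, ReadBatch] = {}
    for sample in counts.counts.columns:
        reads: list[str] = []
        col = counts.counts[sample]
        for sgid, c in col.items():
            spacer = spacer_of[sgid]
            for _ in range(int(c)):
                sp = spacer
                if error_rate > 0 and rng.random() < error_rate:
                    sp = _mutate_one_base(sp, rng)
                pad5 = "".join(rng.choice(_BASES, size=pad_length))
                pad3 = "".join(rng.choice(_BASES, size=pad_length))
                reads.append(pad5 + flank5 + sp + flank3 + pad3)
        rng.shuffle(reads)
        batches[sample] = ReadBatch(reads=reads, flank5=flank5, flank3=flank3)
    return batches
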