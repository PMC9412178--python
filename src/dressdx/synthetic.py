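"""Synthetic cohorts with the statistical structure the pipeline assumes.

Two generators emulate the study's two data modalities:

* ``generate_paired_counts`` — a discovery-style paired RNA-seq experiment:
  negative-binomial counts for drug/media sample pairs, gene-wise mean
  abundances drawn log-normally, a per-subject library-size effect, and a
  drug-induced signature (log2 fold-change ``effect_logfc``, roughly
  balanced up/down) planted in allergic subjects only. Signature genes are
  planted on well-expressed genes, since the downstream selection cascade
  requires minimum abundance and a signature on unexpressed genes would be
  undetectable by design.
* ``generate_qpcr_card`` — a validation-style array card: duplicate Ct
  wells per subject x panel gene x condition, a stable housekeeping gene,
  and target-gene drug-condition Ct shifted by minus the planted log2
  fold-change so the expected log2 RQ equals the planted effect in allergic
  subjects (and 0 in tolerant ones).

``table1_fixture`` carries the in-study comparative T-cell assay values
(LPA stimulation indices and background-corrected IFN-gamma ELISpot counts)
for the discovery, validation, and tolerant cohorts.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import PairedCountMatrix, SignaturePanel

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "AssayFixture",
    "generate_paired_counts",
    "generate_qpcr_card",
    "table1_fixture",
    "assay_positive",
]

# minimum expected media-side cpm for a gene to host a planted signature;
# the selection cascade (min cpm >= 4, max cpm >= 100) cannot recover
# markers planted below its own abundance floor
SIGNATURE_MIN_CPM = 150.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-shaped simulation parameters.

    Defaults mirror the study conditions: 5 discovery / 6 validation
    allergic subjects, 7 tolerant controls, ~12k expressed genes, a planted
    drug effect of |log2 FC| = 2 balanced up/down, and duplicate qPCR wells
    with 0.1-cycle log2-RQ technical noise.
    """

    n_allergic: int = 5
    n_tolerant: int = 7
    n_genes: int = 12_000
    n_signature_genes: int = 22
    effect_logfc: float = 2.0
    frac_down: float = 0.5
    nb_dispersion: float = 0.1
    libsize_range: tuple[float, float] = (500_000.0, 2_000_000.0)
    qpcr_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_allergic < 1:
            raise ValueError("need at least one allergic subject")
        if self.n_tolerant < 0:
            raise ValueError("n_tolerant must be non-negative")
        if self.n_genes < 1 or self.n_signature_genes < 0:
            raise ValueError("gene counts must be positive")
        if self.n_signature_genes > self.n_genes:
            raise ValueError("n_signature_genes cannot exceed n_genes")
        if self.effect_logfc < 0:
            raise ValueError("effect_logfc must be >= 0")
        if not 0 <= self.frac_down <= 1:
            raise ValueError("frac_down must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        lo, hi = self.libsize_range
        if lo <= 0 or hi < lo:
            raise ValueError("libsize_range must be positive and ordered")
        if self.qpcr_noise_sd < 0:
            raise ValueError("qpcr_noise_sd must be >= 0")

    @classmethod
    def discovery(cls, **overrides) -> "SyntheticConfig":
        """The discovery cohort: 5 allergic subjects, paired RNA-seq only."""
        return cls(**{"n_allergic": 5, "n_tolerant": 0, **overrides})

    @classmethod
    def validation(cls, **overrides) -> "SyntheticConfig":
        """The validation card cohort: 6 allergic and 7 tolerant subjects."""
        return cls(**{"n_allergic": 6, "n_tolerant": 7, **overrides})


@dataclass(frozen=True)
class GroundTruth:
    """Planted signature: gene ids, directions (+1/-1), and log2 FC."""

    signature_gene_ids: tuple[str, ...]
    directions: dict[str, int] = field(hash=False)
    logfc: dict[str, float] = field(hash=False)


@dataclass(frozen=True)
class AssayFixture:
    """One cohort's comparative T-cell assay values.

    ``ifn_corrected`` entries are background-corrected maxima in
    spot-forming units, or None where the assay was recorded negative.
    """

    cohort: str
    lpa_si: tuple[float, ...]
    ifn_corrected: tuple[float | None, ...]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.lpa_si):
            raise ValueError("stimulation indices must be >= 0")
        if len(self.lpa_si) != len(self.ifn_corrected):
            raise ValueError("assay vectors must be aligned per subject")


def _subject_ids(config: SyntheticConfig) -> tuple[list[str], list[str]]:
    allergic = [f"A{i + 1:02d}" for i in range(config.n_allergic)]
    tolerant = [f"T{i + 1:02d}" for i in range(config.n_tolerant)]
    return allergic, tolerant


def _gene_means(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    # log-normal abundance on the counts scale (meanlog 3, sdlog 1.5)
    return rng.lognormal(mean=3.0, sigma=1.5, size=config.n_genes)


def _plant_signature(
    config: SyntheticConfig, rng: np.random.Generator, mu: np.ndarray, gene_ids: list[str]
) -> GroundTruth:
    rel_cpm = mu / mu.sum() * 1e6
    eligible = np.flatnonzero(rel_cpm >= SIGNATURE_MIN_CPM)
    if len(eligible) < config.n_signature_genes:
        # fall back to the most abundant genes if the draw was light-tailed
        eligible = np.argsort(rel_cpm)[::-1][: max(config.n_signature_genes, 1)]
    idx = rng.choice(eligible, size=config.n_signature_genes, replace=False)
    n_down = int(round(config.frac_down * config.n_signature_genes))
    dirs = np.array([-1] * n_down + [1] * (config.n_signature_genes - n_down))
    rng.shuffle(dirs)
    ids = tuple(gene_ids[i] for i in idx)
    return GroundTruth(
        signature_gene_ids=ids,
        directions={g: int(s) for g, s in zip(ids, dirs)},
        logfc={g: float(s * config.effect_logfc) for g, s in zip(ids, dirs)},
    )


def generate_paired_counts(
    config: SyntheticConfig,
) -> tuple[PairedCountMatrix, GroundTruth]:
    """Paired drug/media NB count matrix with a planted allergic-only signature.

    Deterministic given ``config.seed``; one drug and one media column per
    subject; tolerant subjects carry no planted effect.
    """
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    mu = _gene_means(config, rng)
    truth = _plant_signature(config, rng, mu, gene_ids)
    sig_idx = np.array([gene_ids.index(g) for g in truth.signature_gene_ids], dtype=int)
    sig_mult = np.array(
        [2.0 ** truth.logfc[g] for g in truth.signature_gene_ids], dtype=float
    )

    allergic, tolerant = _subject_ids(config)
    lo, hi = config.libsize_range
    log_lo, log_hi = np.log(lo), np.log(hi)
    columns: dict[str, np.ndarray] = {}
    design_rows = []
    q = mu / mu.sum()
    for group, subjects in (("allergic", allergic), ("tolerant", tolerant)):
        for subj in subjects:
            # per-subject log-normal library scaling, clipped into range
            lib = float(
                np.clip(
                    rng.lognormal(mean=(log_lo + log_hi) / 2, sigma=(log_hi - log_lo) / 4),
                    lo,
                    hi,
                )
            )
            for cond in ("media", "drug"):
                mean = q * lib
                if group == "allergic" and cond == "drug" and config.effect_logfc > 0:
                    mean = mean.copy()
                    mean[sig_idx] = mean[sig_idx] * sig_mult
                r = 1.0 / config.nb_dispersion
                counts = rng.negative_binomial(n=r, p=r / (r + mean))
                sample = f"{subj}_{cond}"
                columns[sample] = counts
                design_rows.append((sample, subj, cond, group))

    counts_df = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    design = pd.DataFrame(
        design_rows, columns=["sample", "subject", "condition", "group"]
    ).set_index("sample")
    return PairedCountMatrix(counts=counts_df, design=design), truth


def generate_qpcr_card(
    config: SyntheticConfig, panel: SignaturePanel
) -> tuple[pd.DataFrame, GroundTruth]:
    """Duplicate-well Ct card for the panel over allergic and tolerant subjects.

    Allergic target genes have their drug-condition Ct shifted by minus the
    planted log2 FC (panel direction x effect_logfc), so the expected log2 RQ
    equals the planted effect; tolerant subjects are unshifted. Every
    replicate well (targets and housekeeping) carries Gaussian Ct noise of
    sd = qpcr_noise_sd / sqrt(2), which propagates through replicate
    collapse and double-delta-Ct to a log2-RQ sd of exactly qpcr_noise_sd.
    """
    if panel.housekeeping_gene_id in panel.gene_ids:
        raise ValueError("panel housekeeping gene must be distinct")
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth(
        signature_gene_ids=tuple(panel.gene_ids),
        directions=dict(panel.directions),
        logfc={g: float(d * config.effect_logfc) for g, d in panel.directions.items()},
    )
    allergic, tolerant = _subject_ids(config)
    base_ct = {g: float(rng.uniform(22.0, 30.0)) for g in panel.gene_ids}
    hk = panel.housekeeping_gene_id
    base_ct[hk] = 20.0
    well_sd = config.qpcr_noise_sd / np.sqrt(2.0)

    rows = []
    for group, subjects in (("allergic", allergic), ("tolerant", tolerant)):
        for subj in subjects:
            subj_shift = float(rng.normal(0.0, 0.5))  # loading/RT offset, cancels in dCt
            for gene in [hk, *panel.gene_ids]:
                for cond in ("media", "drug"):
                    ct = base_ct[gene] + subj_shift
                    if gene != hk and group == "allergic" and cond == "drug":
                        ct -= truth.logfc[gene]  # one cycle ~ one log2 unit
                    for rep in (1, 2):
                        noise = rng.normal(0.0, well_sd) if well_sd > 0 else 0.0
                        rows.append((subj, gene, cond, rep, ct + noise))
    card = pd.DataFrame(rows, columns=["subject", "gene", "condition", "replicate", "ct"])
    return card, truth


# Comparative T-cell assay values (LPA maximal stimulation index; IFN-gamma
# background-corrected maximum, SFU; None = recorded negative).
_TABLE1 = {
    "discovery": (
        (69.9, 63.4, 7.67, 50.4, 18.5),
        (254.0, 74.0, 10.0, 175.0, 111.0),
    ),
    "validation": (
        (13.7, 3.6, 2.3, 2.5, 18.4, 1.3),
        (20.0, 21.0, 39.0, 554.0, 113.0, 605.0),
    ),
    "tolerant": (
        (1.7, 0.7, 2.1, 0.6, 1.4, 1.2, 0.8),
        (None, None, None, None, None, None, None),
    ),
}


def table1_fixture() -> dict[str, AssayFixture]:
    """The study cohorts' printed LPA / IFN-gamma ELISpot values."""
    return {
        cohort: AssayFixture(cohort=cohort, lpa_si=lpa, ifn_corrected=ifn)
        for cohort, (lpa, ifn) in _TABLE1.items()
    }


def assay_positive(si: float, ifn_corrected: float | None) -> tuple[bool, bool]:
    """Per-assay positivity: LPA positive iff SI > 2 (strict); ELISpot
    positive iff a corrected value is present and > 0."""
    if si < 0:
        raise ValueError("stimulation index must be >= 0")
    lpa_pos = si > 2.0
    ifn_pos = ifn_corrected is not None and ifn_corrected > 0
    return lpa_pos, ifn_pos


def ifn_rank_values(fixture: AssayFixture) -> list[float]:
    """ELISpot values for rank tests: negative entries enter rank-minimal (0)."""
    return [0.0 if v is None else float(v) for v in fixture.ifn_corrected]
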