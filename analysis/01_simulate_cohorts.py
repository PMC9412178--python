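#!/usr/bin/env python
"""Simulate the study-shaped cohorts used by the downstream analyses.

Writes under results/data/:
  discovery/  — paired drug/media counts for a signature-recovery cohort
                (16 subjects x 2 conditions, 2000 genes, 22 planted markers
                at |log2 FC| = 2) plus its ground truth;
  discovery_study_scale/ — the 5-subject cohort matching the study's actual
                discovery size (used to show what that size can and cannot
                support under exact permutation inference);
  validation/ — a duplicate-well qPCR card for 6 allergic + 7 tolerant
                subjects over the shipped 6-gene panel, noise 0.1 cycles.
"""
import json
from pathlib import Path

from dressdx import SyntheticConfig, default_panel, generate_paired_counts, generate_qpcr_card
from dressdx._io import write_counts, write_json, write_qpcr_card

SEED = 1
OUT = Path("results/data")


def dump_truth(truth, path: Path) -> None:
    write_json(
        {
            "signature_gene_ids": list(truth.signature_gene_ids),
            "directions": truth.directions,
            "logfc": truth.logfc,
        },
        path,
    )


def main() -> None:
    recovery = SyntheticConfig.discovery(
        n_allergic=16, n_genes=2000, n_signature_genes=22, effect_logfc=2.0, seed=SEED
    )
    pcm, truth = generate_paired_counts(recovery)
    d = OUT / "discovery"
    write_counts(pcm, d / "counts.tsv", d / "design.csv")
    dump_truth(truth, d / "ground_truth.json")
    print(f"discovery (recovery scale): {pcm.counts.shape[0]} genes x "
          f"{pcm.counts.shape[1]} samples, 22 planted markers -> {d}")

    study = SyntheticConfig.discovery(n_genes=2000, n_signature_genes=22, seed=SEED)
    pcm5, truth5 = generate_paired_counts(study)
    d5 = OUT / "discovery_study_scale"
    write_counts(pcm5, d5 / "counts.tsv", d5 / "design.csv")
    dump_truth(truth5, d5 / "ground_truth.json")
    print(f"discovery (study scale): {pcm5.counts.shape[1]} samples (5 pairs) -> {d5}")

    panel = default_panel()
    validation = SyntheticConfig.validation(qpcr_noise_sd=0.1, effect_logfc=2.0, seed=SEED)
    card, truth_v = generate_qpcr_card(validation, panel)
    v = OUT / "validation"
    write_qpcr_card(card, v / "qpcr_card.csv")
    dump_truth(truth_v, v / "ground_truth.json")
    print(f"validation: {card.subject.nunique()} subjects x "
          f"{card.gene.nunique()} genes (duplicate wells) -> {v}")


if __name__ == "__main__":
    main()
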