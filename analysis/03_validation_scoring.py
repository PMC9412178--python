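#!/usr/bin/env python
"""Validation workflow: array card -> log2 RQ -> concordance scores ->
diagnostic evaluation of allergic vs tolerant subjects.

Reads results/data/validation/qpcr_card.csv and the shipped 6-gene panel;
writes results/validation/: rq.tsv, scores.tsv, evaluation.json.
The reduced panel is scored at its zero threshold with the strict (> 0)
positivity convention.
"""
from pathlib import Path

from dressdx import default_panel, run_validation
from dressdx._io import read_qpcr_card, write_json

OUT = Path("results/validation")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    card = read_qpcr_card("results/data/validation/qpcr_card.csv")
    panel = default_panel()
    res = run_validation(card, panel, threshold=0, inclusive=False)

    res["rq"].to_csv(OUT / "rq.tsv", sep="\t", index=False)
    res["scores"].to_csv(OUT / "scores.tsv", sep="\t", index=False)
    ev = res["evaluation"]
    write_json(
        {
            "confusion": {
                "tp": ev["confusion"].tp,
                "fn": ev["confusion"].fn,
                "fp": ev["confusion"].fp,
                "tn": ev["confusion"].tn,
            },
            "sensitivity": float(ev["sensitivity"]),
            "specificity": float(ev["specificity"]),
            "fisher_p": ev["fisher_p"],
            "mwu_p": ev["mwu_p"],
            "threshold": ev["threshold"],
            "threshold_inclusive": ev["threshold_inclusive"],
        },
        OUT / "evaluation.json",
    )

    print(res["scores"].to_string(index=False))
    print(
        f"\n6-gene panel, threshold 0 (strict): sensitivity "
        f"{float(ev['sensitivity']):.1%}, specificity {float(ev['specificity']):.1%}, "
        f"Fisher p = {ev['fisher_p']:.4g}, Mann-Whitney p = {ev['mwu_p']:.4g}"
    )


if __name__ == "__main__":
    main()
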