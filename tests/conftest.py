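import numpy as np
import pandas as pd
import pytest

from dressdx import PairedCountMatrix, SignatureGene, SignaturePanel


@pytest.fixture
def small_pcm() -> PairedCountMatrix:
    """Deterministic 6-gene x 3-pair count matrix."""
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(6)]
    samples, rows = {}, []
    for subj in ("s1", "s2", "s3"):
        for cond in ("drug", "media"):
            name = f"{subj}_{cond}"
            samples[name] = rng.integers(0, 200, size=6)
            rows.append((name, subj, cond, "allergic"))
    counts = pd.DataFrame(samples, index=pd.Index(genes, name="gene_id"))
    design = pd.DataFrame(rows, columns=["sample", "subject", "condition", "group"]).set_index(
        "sample"
    )
    return PairedCountMatrix(counts=counts, design=design)


@pytest.fixture
def six_gene_panel() -> SignaturePanel:
    return SignaturePanel(
        genes=[
            SignatureGene("STAC", 1),
            SignatureGene("GPR183", -1),
            SignatureGene("CD40", 1),
            SignatureGene("CISH", 1),
            SignatureGene("CD4", -1),
            SignatureGene("CCL8", 1),
        ],
        housekeeping_gene_id="YWHAZ",
    )
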