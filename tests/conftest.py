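import numpy as np
import pandas as pd
import pytest

from screenma import ScreenCountTable, SgRNARecord, SyntheticScreenConfig, simulate_screen


@pytest.fixture
def toy_library():
    """12 guides: 2 target genes x 4 guides + 1 control gene x 4 guides."""
    recs = []
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    seen = set()
    for gene, ctrl in [("TP53", False), ("CDKN1A", False), ("NEG01", True)]:
        for k in range(4):
            while True:
                sp = "".join(rng.choice(bases, size=19))
                if sp not in seen:
                    seen.add(sp)
                    break
            recs.append(SgRNARecord(f"{gene}_sg{k+1}", sp, gene, ctrl))
    return recs


@pytest.fixture
def toy_table(toy_library):
    rng = np.random.default_rng(11)
    ids = [r.sgrna_id for r in toy_library]
    counts = pd.DataFrame(
        rng.integers(50, 500, size=(len(ids), 4)),
        index=pd.Index(ids, name="sgrna_id"),
        columns=["pre_r1", "ind_r1", "pre_r2", "ind_r2"],
    )
    samples = pd.DataFrame(
        [
            ("pre_r1", "pre_induction", "r1", None),
            ("ind_r1", "induced", "r1", "pre_r1"),
            ("pre_r2", "pre_induction", "r2", None),
            ("ind_r2", "induced", "r2", "pre_r2"),
        ],
        columns=["sample_id", "condition", "replicate_id", "paired_control_id"],
    )
    return ScreenCountTable(counts=counts, samples=samples)


# one small screen reused by several test modules; module-level geometry kept
# tiny so the whole suite stays fast
SMALL_CONFIG = dict(
    n_genes=60,
    sgrnas_per_gene=8,
    n_control_genes=10,
    controls_sgrnas_per_gene=8,
    depth=300.0,
    seed=42,
)


@pytest.fixture(scope="session")
def small_screen():
    cfg = SyntheticScreenConfig(**SMALL_CONFIG)
    table, truth, library = simulate_screen(cfg)
    return table, truth, library
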