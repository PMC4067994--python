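import numpy as np
import pytest

from otocnv import (
    GeneInfo,
    PanelDefinition,
    RatioMatrix,
    TargetInterval,
    demo_panel,
)


@pytest.fixture(scope="session")
def panel():
    return demo_panel()


@pytest.fixture(scope="session")
def tiny_panel():
    """Two genes on one chromosome: GA (4 exons) and GB (3 exons)."""
    targets = []
    pos = 1000
    for gene, n in [("GA", 4), ("GB", 3)]:
        for k in range(1, n + 1):
            targets.append(
                TargetInterval("chr1", pos, pos + 100, gene, k, f"{gene}_{k}")
            )
            pos += 300
    return PanelDefinition(
        name="tiny", targets=targets, genes=[GeneInfo("GA"), GeneInfo("GB")]
    )


def make_ratio_matrix(panel, per_sample: dict[str, dict[str, float]], mask=()):
    """Build a RatioMatrix directly: {sample: {target_id: ratio}}, default 1."""
    samples = list(per_sample)
    tids = panel.target_ids()
    R = np.ones((len(samples), len(tids)))
    for i, s in enumerate(samples):
        for tid, v in per_sample[s].items():
            R[i, tids.index(tid)] = v
    mask_arr = np.zeros(len(tids), dtype=bool)
    for tid in mask:
        mask_arr[tids.index(tid)] = True
    return RatioMatrix(
        samples=samples,
        batches=["b0"] * len(samples),
        target_ids=tids,
        ratio=R,
        mask=mask_arr,
    )
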