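import numpy as np
import pytest

from splicemod.formats_io import AnnotationModel, Transcript
from splicemod.pipeline import RunConfig, run_end_to_end
from splicemod.simulate import SimConfig, simulate_dataset


@pytest.fixture
def toy_annotation() -> AnnotationModel:
    """Two three-exon transcripts (one per strand) and a single-exon gene.

    Plus-strand tx1: exons (101,200), (401,500), (801,900) -> introns
    (201,400) and (501,800).  Minus-strand tx2 mirrors the layout further
    downstream.
    """
    model = AnnotationModel()
    model.add(Transcript("tx1", "g1", "chrT", "+", [(101, 200), (401, 500), (801, 900)]))
    model.add(Transcript("tx2", "g2", "chrT", "-", [(1101, 1200), (1401, 1500), (1801, 1900)]))
    model.add(Transcript("tx3", "g3", "chrT", "+", [(2101, 2200)]))
    return model


@pytest.fixture
def toy_genome(toy_annotation) -> dict[str, str]:
    """Deterministic sequence long enough for the toy annotation."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    return {"chrT": "".join(rng.choice(bases, size=2500))}


@pytest.fixture(scope="session")
def sim_run(tmp_path_factory):
    """A small simulated dataset and a completed pipeline run over it."""
    root = tmp_path_factory.mktemp("simrun")
    data = simulate_dataset(SimConfig(n_loci=250, seed=11), root / "data")
    config = RunConfig.default_for(data, root / "out", seed=11, n_background=400)
    run_end_to_end(config)
    return {"data": data, "out": root / "out", "config": config}
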