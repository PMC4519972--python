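import pytest

from svmap.pipeline import RunConfig, run_all
from svmap.simulate import SimConfig, simulate_parental_genomes, simulate_read_pairs
from svmap.svcall import call_svs, fit_insert_model


TINY_SIM = dict(
    n_chromosomes=2, chromosome_length=100_000, scaffolds_per_chromosome=1,
    sv_counts={"deletion": 2, "insertion": 2, "duplication": 1,
               "inversion": 1, "complex": 1},
    seed=7,
)


class TinyStudy:
    """One small simulated study shared (read-only) across test modules."""

    def __init__(self):
        self.config = SimConfig(**TINY_SIM)
        self.genomes = simulate_parental_genomes(self.config)
        self.pairs = simulate_read_pairs(self.genomes)
        self.model = fit_insert_model(self.pairs)
        self.calls = call_svs(self.pairs, self.model)


@pytest.fixture(scope="session")
def tiny():
    return TinyStudy()


@pytest.fixture(scope="session")
def mini_run(tmp_path_factory):
    """A complete pipeline run on a small three-chromosome genome."""
    cfg = RunConfig.from_dict({
        "simulate": {
            "n_chromosomes": 3, "chromosome_length": 120_000,
            "scaffolds_per_chromosome": 2,
            "sv_counts": {"deletion": 8, "insertion": 10, "duplication": 1,
                          "inversion": 1, "complex": 1},
            "n_progeny": 150, "seed": 11,
        },
    })
    outdir = tmp_path_factory.mktemp("mini_run")
    results = run_all(cfg, outdir)
    results["outdir"] = outdir
    return results
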