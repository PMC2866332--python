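"""Shared fixtures.

The heavyweight fixtures simulate one study at the documented
conditions (100 clones, ~2 kb mean, 14% with a sub-read-length exon,
uniform-ish 50x coverage, 0.5% substitution error) and run the full
pipeline once per session; several tests read different aspects of the
same run.
"""

from __future__ import annotations

import numpy as np
import pytest

from clonefinish.aligner import Genome
from clonefinish.pipeline import run_assemble, run_evaluate, reference_structures
from clonefinish.core import Params
from clonefinish.simulate import (
    SimConfig,
    debruijn_contigs,
    generate_world,
    sanger_ends,
    shotgun_reads,
)

STUDY_SEED = 11


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def small_study():
    """A 10-clone study on a 300 kb genome — fast enough for unit-level
    pipeline checks."""
    cfg = SimConfig(
        seed=5, n_clones=10, genome_len=300_000, pcr_success=1.0,
        amplification_sigma=0.2, mean_coverage=50.0,
    )
    world = generate_world(cfg)
    reads = shotgun_reads(world)
    sanger = sanger_ends(world)
    contigs = debruijn_contigs(reads)
    genome = Genome(world.genome)
    return dict(cfg=cfg, world=world, reads=reads, sanger=sanger,
                contigs=contigs, genome=genome)


@pytest.fixture(scope="session")
def study():
    """The full-scale study: 100 clones at uniform-ish 50x coverage with
    every clone PCR-amplified."""
    cfg = SimConfig(
        seed=STUDY_SEED, n_clones=100, pcr_success=1.0,
        amplification_sigma=0.2, mean_coverage=50.0, subst_error=0.005,
    )
    world = generate_world(cfg)
    reads = shotgun_reads(world)
    sanger = sanger_ends(world)
    contigs = debruijn_contigs(reads)
    genome = Genome(world.genome)
    return dict(cfg=cfg, world=world, reads=reads, sanger=sanger,
                contigs=contigs, genome=genome)


@pytest.fixture(scope="session")
def study_run(study):
    """Assembly + evaluation of the full-scale study."""
    world = study["world"]
    genome = study["genome"]
    result = run_assemble(genome, study["contigs"], study["reads"],
                          study["sanger"])
    cds_ranges = {c.clone_id: (c.cds_start, c.cds_end) for c in world.clones}
    ref_structs = reference_structures(
        world.clone_seqs(), cds_ranges, genome, Params()
    )
    ev = run_evaluate(result, world.clone_seqs(), cds_ranges, genome,
                      study["reads"], ref_structs=ref_structs)
    return dict(result=result, eval=ev, cds_ranges=cds_ranges,
                ref_structs=ref_structs)
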