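"""Shared fixtures: a small simulated panel and lightweight reference stubs."""

from __future__ import annotations

import numpy as np
import pytest

from capmut.formats import PairedVariantCall, read_fasta
from capmut.simulate import SimulationConfig, simulate_panel


class DictReference:
    """In-memory reference with the fetch/length interface of ReferenceGenome."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences = {k: v.upper() for k, v in sequences.items()}

    @property
    def chroms(self):
        return list(self.sequences)

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.sequences[chrom]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(f"fetch {chrom}:{start}-{end} out of bounds")
        return seq[start:end]


@pytest.fixture
def dict_reference():
    return DictReference


def make_call(**overrides) -> PairedVariantCall:
    """A well-formed paired call with sensible defaults, field-overridable."""
    fields = dict(
        chrom="chr1",
        pos=100,
        ref="C",
        alt="T",
        tumor_genotype=("C", "T"),
        normal_genotype=("C", "C"),
        tumor_ref_reads=60,
        tumor_alt_reads=40,
        normal_ref_reads=80,
        normal_alt_reads=0,
        call_quality=500.0,
        qd=12.0,
        hrun=1,
        fs=5.0,
        read_pos_rank_sum=0.5,
    )
    fields.update(overrides)
    return PairedVariantCall(**fields)


@pytest.fixture
def call_factory():
    return make_call


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=11, n_genes=6)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return simulate_panel(small_config)


@pytest.fixture(scope="session")
def panel_files(small_panel, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("panel")
    return small_panel.write(outdir)


@pytest.fixture(scope="session")
def panel_reference(panel_files):
    return read_fasta(panel_files["reference"])


def random_calls(n: int, seed: int) -> list[PairedVariantCall]:
    """Random paired calls spanning all classifier-relevant regimes."""
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    calls = []
    for _ in range(n):
        ref = bases[rng.integers(4)]
        alt = bases[rng.integers(4)]
        while alt == ref:
            alt = bases[rng.integers(4)]
        if rng.random() < 0.3:  # indel
            if rng.random() < 0.5:
                ref = ref + "".join(rng.choice(list(bases), size=rng.integers(1, 5)))
                alt = ref[0]
            else:
                alt = ref + "".join(rng.choice(list(bases), size=rng.integers(1, 5)))
        gt_choices = [(ref, ref), (ref, alt), (alt, alt)]
        calls.append(
            PairedVariantCall(
                chrom="chr1",
                pos=int(rng.integers(1, 10_000)),
                ref=ref,
                alt=alt,
                tumor_genotype=gt_choices[rng.integers(3)],
                normal_genotype=gt_choices[rng.integers(3)],
                tumor_ref_reads=int(rng.integers(0, 200)),
                tumor_alt_reads=int(rng.integers(0, 200)),
                normal_ref_reads=int(rng.integers(0, 30)),
                normal_alt_reads=int(rng.integers(0, 4)),
                call_quality=float(rng.uniform(0, 100)),
                qd=None if rng.random() < 0.2 else float(rng.uniform(0, 10)),
                hrun=None if rng.random() < 0.2 else int(rng.integers(0, 10)),
                fs=None if rng.random() < 0.2 else float(rng.uniform(0, 400)),
                read_pos_rank_sum=None if rng.random() < 0.3 else float(rng.uniform(-30, 10)),
            )
        )
    return calls
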