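import numpy as np
import pytest

from pitescan import PiRNA, SeedSpec, SimConfig, TERecord, simulate

#: 28-nt zebrafish-style piRNA used as the canonical worked example.
CANONICAL_PIRNA = "TACACGAAGACTGTGGTGTGATTGGGCG"


def make_te(name="TE-1", family="Gypsy", te_class="LTR", chrom="chr1",
            start=0, end=None, strand="+", sequence="ACGTACGTACGTACGT"):
    if end is None and start is not None:
        end = start + len(sequence)
    return TERecord(name=name, family=family, te_class=te_class, chrom=chrom,
                    start=start, end=end, strand=strand, sequence=sequence)


def random_te_reference(rng: np.random.Generator, n_te: int, te_len_range):
    """In-memory random reference; sequences i.i.d. uniform ACGT."""
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    records = []
    families = ["Gypsy", "L1", "hAT", "Helitron", "Alu", "MOSAT", "FooBar"]
    classes = ["LTR", "LINE", "DNA", "RC", "SINE", "Satellite", "Unclassified"]
    for i in range(n_te):
        length = int(rng.integers(te_len_range[0], te_len_range[1] + 1))
        seq = bases[rng.integers(0, 4, size=length)].tobytes().decode()
        j = int(rng.integers(0, len(families)))
        records.append(make_te(name=f"{families[j]}-{i}", family=families[j],
                               te_class=classes[j], start=i * 5000,
                               sequence=seq))
    return records


def random_pirna(rng: np.random.Generator, length: int, name="pi") -> PiRNA:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return PiRNA(name, bases[rng.integers(0, 4, size=length)].tobytes().decode())


@pytest.fixture
def canonical_pirna() -> PiRNA:
    return PiRNA("dre-piRNA-589795", CANONICAL_PIRNA)


@pytest.fixture
def default_spec() -> SeedSpec:
    return SeedSpec()


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """One shared default-configuration fixture bundle (seed 7)."""
    outdir = tmp_path_factory.mktemp("simbundle")
    return simulate(SimConfig(rng_seed=7), outdir)
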