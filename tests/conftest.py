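import pytest

from tenet.model import SpeciesAnnotation, TECopy
from tenet.synthetic import HitModelConfig, LandscapeConfig, simulate_hits, simulate_landscape


def make_copy(copy_id, genome="g1", family="famA", superfamily="DNA/TcMar-Tc1",
              start=0, length=1000, strand="+", seq="chr1"):
    return TECopy(copy_id=copy_id, genome_id=genome, seq_id=seq, start=start,
                  end=start + length, strand=strand, family=family,
                  superfamily=superfamily)


@pytest.fixture
def tiny_landscape():
    """Small deterministic landscape used across modules (8 species, 2 clades)."""
    cfg = LandscapeConfig(seed=11, n_species=8, n_clades=2,
                          fam_mean=6.0, copy_mean=6.0)
    return simulate_landscape(cfg)


@pytest.fixture
def ssn_copies():
    """Six clade-shared families' worth of copies for SSN-level tests."""
    cfg = LandscapeConfig(seed=2, n_species=8, n_clades=2,
                          fam_mean=5.0, copy_mean=10.0)
    land = simulate_landscape(cfg)
    fams = sorted({c.family for c in land.copies
                   if c.family.startswith("clade")})[:6]
    return [c for c in land.copies if c.family in fams]


@pytest.fixture
def ssn_hitset(ssn_copies):
    return simulate_hits(ssn_copies, HitModelConfig(seed=7))
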