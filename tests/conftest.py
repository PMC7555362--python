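import numpy as np
import pytest

from igkit.numbering import C_TOPOLOGY, V_TOPOLOGY, assign_numbering
from igkit.simulate import SimConfig, make_toy_germline, simulate_repertoire


def build_vh(cdr_lengths=(8, 8, 13), fr_lengths=(25, 17, 38, 11),
             seed=7):
    """A hallmark-complete VH-like domain with the requested region
    lengths (sequence content is arbitrary except at hallmark sites)."""
    rng = np.random.default_rng(seed)
    aa = "ACDEFGHIKLMNPQRSTVWY"

    def rand(n, forbid="C"):
        pool = [a for a in aa if a not in forbid]
        return "".join(pool[rng.integers(len(pool))] for _ in range(n))

    f1, f2, f3, f4 = fr_lengths
    c1, c2, c3 = cdr_lengths
    # hallmark offsets inside each region for canonical lengths
    # C lands at position 23 whether FR1 is 25 (gap at 10) or 26 (complete)
    fr1 = rand(f1 - 4) + "C" + rand(3)
    fr2 = rand(2) + "W" + rand(f2 - 3)            # W at 41
    # FR3 spans 66-104 with gap at 73; position 89 is its 23rd residue
    fr3 = rand(22) + "V" + rand(f3 - 24) + "C"    # hydrophobic 89, C 104
    fr4 = "WG" + rand(1) + "G" + rand(f4 - 4)     # J-TRP + J-MOTIF
    seq = fr1 + rand(c1) + fr2 + rand(c2) + fr3 + rand(c3) + fr4
    boundaries = (f1, c1, f2, c2, f3, c3, f4)
    return assign_numbering(seq, boundaries, V_TOPOLOGY)


def build_c_domain(seed=11, boundaries=(15, 2, 11, 10, 7, 5, 8, 4, 12, 2,
                                        8, 7, 11)):
    rng = np.random.default_rng(seed)
    aa = "ADEFGHIKLMNPQRSTVY"

    def rand(n):
        return "".join(aa[rng.integers(len(aa))] for _ in range(n))

    # boundaries: A AB B BC C CD D DE E EF F FG G
    a, ab, b, bc, c, cd, d, de, e, ef, f, fg, g = boundaries
    seq = (rand(a) + rand(ab)
           + rand(7) + "C" + rand(3)              # C at 23 (B: 16-26)
           + rand(bc)
           + rand(2) + "W" + rand(c - 3)          # W at 41 (C: 39-45)
           + rand(cd) + rand(d) + rand(de)
           + rand(4) + "L" + rand(e - 5)          # hydrophobic 89 (E: 85-96)
           + rand(ef)
           + rand(f - 1) + "C"                    # C at 104 (F: 97-104)
           + rand(fg) + rand(g))
    return assign_numbering(seq, boundaries, C_TOPOLOGY)


@pytest.fixture(scope="session")
def vh_domain():
    return build_vh()


@pytest.fixture(scope="session")
def c_domain():
    return build_c_domain()


@pytest.fixture(scope="session")
def sim_setup():
    """Toy germline plus a seeded repertoire sharing one RNG stream."""
    config = SimConfig(seed=42, n_clones=30)
    rng = np.random.default_rng(config.seed)
    germline = make_toy_germline(config, rng)
    records = simulate_repertoire(config, germline)
    return config, germline, records
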