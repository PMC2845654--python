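import dendropy
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"


def random_orf_locus(rng: np.random.Generator, n_codons: int = 120, flank: int = 20):
    """A random sequence holding one intact ORF, with flanks.

    Returns (sequence, orf_start). Internal codons avoid stops and ATG so the
    planted ORF is the unique scan hit of its length.
    """
    codons = []
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(list(_BASES), size=3))
        if c not in _STOPS and c != "ATG":
            codons.append(c)
    orf = "ATG" + "".join(codons) + "TAA"
    # stop-rich flanks: "TAGA" tiling carries a stop in every reading frame,
    # so no accidental ORF can outgrow the planted one
    pad = ("TAGA" * (flank // 4 + 1))[:flank]
    return pad + orf + pad, flank


@pytest.fixture
def primate_tree() -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data="(((human,chimp),gorilla),(orangutan,rhesus));", schema="newick"
    )
    tree.is_rooted = True
    return tree


@pytest.fixture
def mammal_tree() -> dendropy.Tree:
    """An 8-leaf tree mirroring a hominoid-within-mammals phylogeny."""
    tree = dendropy.Tree.get(
        data="((((((human,chimp),gorilla),orangutan),gibbon),rhesus),(mouse,dog));",
        schema="newick",
    )
    tree.is_rooted = True
    return tree


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
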