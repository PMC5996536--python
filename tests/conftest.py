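import numpy as np
import pandas as pd
import pytest

from pedlink.pedigree import (
    Individual,
    MarkerMap,
    Pedigree,
    Phenotype,
    Sex,
    recode_phenotypes,
)


def make_map(freqs1=(0.6,), chrom="1", spacing=1.0):
    """MarkerMap with one marker per entry of freqs1."""
    rows = [
        {
            "marker": f"m{k + 1}",
            "chrom": chrom,
            "cm": k * spacing,
            "freq1": f,
            "freq2": 1.0 - f,
        }
        for k, f in enumerate(freqs1)
    ]
    return MarkerMap(pd.DataFrame(rows))


def make_ind(iid, father, mother, sex, phen, genotypes):
    """genotypes: list of (a, b) allele-code pairs, 0 = missing."""
    return Individual(
        iid,
        father,
        mother,
        Sex(sex),
        Phenotype(phen),
        np.asarray(genotypes, dtype=np.int16).reshape(-1, 2),
    )


def make_pedigree(pid, rows):
    """rows: (iid, father, mother, sex, phen, genotypes)."""
    return Pedigree(pid, {r[0]: make_ind(*r) for r in rows})


@pytest.fixture
def one_marker_map():
    return make_map((0.6,))


@pytest.fixture
def trio():
    return make_pedigree(
        "t1",
        [
            ("f", "0", "0", 1, 1, [(1, 2)]),
            ("m", "0", "0", 2, 1, [(1, 1)]),
            ("c", "f", "m", 1, 2, [(1, 2)]),
        ],
    )


# ---------------------------------------------------------------------------
# random small pedigrees for the peeling-vs-enumeration oracle
# ---------------------------------------------------------------------------

_STRUCTURES = [
    # (iid, father, mother, sex): trio, quartet, 3-generation, two sibships
    [("f", "0", "0", 1), ("m", "0", "0", 2), ("c1", "f", "m", 1)],
    [("f", "0", "0", 1), ("m", "0", "0", 2), ("c1", "f", "m", 1), ("c2", "f", "m", 2)],
    [
        ("gf", "0", "0", 1), ("gm", "0", "0", 2), ("f", "gf", "gm", 1),
        ("m", "0", "0", 2), ("c1", "f", "m", 1), ("c2", "f", "m", 2),
    ],
    [
        ("gf", "0", "0", 1), ("gm", "0", "0", 2),
        ("a", "gf", "gm", 1), ("b", "gf", "gm", 2),
        ("aw", "0", "0", 2), ("bh", "0", "0", 1),
        ("c1", "a", "aw", 1), ("c2", "bh", "b", 2),
    ],
    [
        ("f", "0", "0", 1), ("m", "0", "0", 2),
        ("c1", "f", "m", 1), ("c2", "f", "m", 2), ("c3", "f", "m", 1),
        ("s", "0", "0", 2), ("g1", "c1", "s", 2),
    ],
]


def random_small_pedigree(rng, max_joint_states=300_000):
    """Random ≤8-member pedigree with Mendel-consistent genotypes.

    Genotypes are gene-dropped so the marker data have positive likelihood;
    the typed fraction is resampled until the joint two-locus state space is
    small enough for direct enumeration.
    """
    struct = _STRUCTURES[rng.integers(len(_STRUCTURES))]
    ids = [s[0] for s in struct]
    while True:
        haps = {}
        for iid, fa, mo, _sex in struct:
            if fa == "0":
                haps[iid] = rng.integers(1, 3, size=2)
            else:
                haps[iid] = np.array(
                    [haps[fa][rng.integers(2)], haps[mo][rng.integers(2)]]
                )
        typed = {iid: rng.random() < 0.75 for iid in ids}
        states = 1
        for iid in ids:
            if not typed[iid]:
                states *= 16
            elif haps[iid][0] != haps[iid][1]:
                states *= 8
            else:
                states *= 4
        if states <= max_joint_states:
            break
    rows = []
    for iid, fa, mo, sex in struct:
        g = tuple(haps[iid]) if typed[iid] else (0, 0)
        phen = int(rng.choice([0, 1, 2]))
        rows.append((iid, fa, mo, sex, phen, [g]))
    ped = make_pedigree("r", rows)
    return recode_phenotypes(ped, "ASD")


def random_trait_model(rng):
    from pedlink.likelihood import TraitModel

    p = float(rng.uniform(0.01, 0.6))
    f = np.sort(rng.uniform(0.0, 1.0, size=3))[::-1]
    return TraitModel(p, *f)
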