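"""Pedigree and marker-map data model with LINKAGE-format I/O.

The in-memory objects mirror the pre-makeped LINKAGE dialect: a PED file with
six leading columns (family, individual, father, mother, sex, phenotype)
followed by two allele columns per marker, and a TSV map file carrying marker
name, chromosome, sex-averaged cM position and the two allele frequencies.

Phenotypes use a four-level coding that extends the classic LINKAGE affection
column with one extra class for the broad autism phenotype (BAP):
``0=unknown, 1=unaffected, 2=ASD, 3=BAP``.  Analysis always runs on a binary
recoding of these four levels (see :func:`recode_phenotypes`).

Pedigrees must be zero-loop (the marriage graph is a tree); loop pedigrees,
including consanguineous matings, are rejected at validation time because the
peeling engine requires loop-free structures.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

FOUNDER = "0"  #: sentinel parent id for founders ("0 0" in LINKAGE files)


class PedigreeError(ValueError):
    """Base class for pedigree parsing/validation failures."""


class ParseError(PedigreeError):
    """Malformed PED or map file row."""


class StructureError(PedigreeError):
    """Referential or sex inconsistency in the pedigree structure."""


class UnsupportedPedigreeError(PedigreeError):
    """Pedigree contains loops (e.g. consanguineous marriage) or other
    structures the peeling engine cannot handle."""


class Sex(enum.IntEnum):
    MALE = 1
    FEMALE = 2


class Phenotype(enum.IntEnum):
    UNKNOWN = 0
    UNAFFECTED = 1
    ASD = 2
    BAP = 3


class Affection(enum.IntEnum):
    """Binary affection status used by the likelihood engine."""

    UNKNOWN = 0
    UNAFFECTED = 1
    AFFECTED = 2


class Trait(str, enum.Enum):
    """The two analysis phenotypes.

    Under ``ASD`` only ASD individuals are affected and BAP individuals are
    coded unaffected; under ``ASD_BAP`` both ASD and BAP count as affected.
    """

    ASD = "ASD"
    ASD_BAP = "ASD_BAP"


_RECODE = {
    Trait.ASD: {
        Phenotype.UNKNOWN: Affection.UNKNOWN,
        Phenotype.UNAFFECTED: Affection.UNAFFECTED,
        Phenotype.ASD: Affection.AFFECTED,
        Phenotype.BAP: Affection.UNAFFECTED,
    },
    Trait.ASD_BAP: {
        Phenotype.UNKNOWN: Affection.UNKNOWN,
        Phenotype.UNAFFECTED: Affection.UNAFFECTED,
        Phenotype.ASD: Affection.AFFECTED,
        Phenotype.BAP: Affection.AFFECTED,
    },
}


@dataclass
class Individual:
    """One pedigree member.

    ``genotypes`` is an ``(n_markers, 2)`` integer array of allele codes with
    0 meaning a missing call; allele order within a pair is arbitrary
    (genotypes are unphased).  ``affection`` is the binary recoding of
    ``phenotype`` under the current analysis trait; it is ``None`` until
    :func:`recode_phenotypes` has been applied.
    """

    individual_id: str
    father_id: str
    mother_id: str
    sex: Sex
    phenotype: Phenotype
    genotypes: np.ndarray
    affection: Affection | None = None

    @property
    def is_founder(self) -> bool:
        return self.father_id == FOUNDER and self.mother_id == FOUNDER

    def copy(self) -> "Individual":
        return replace(self, genotypes=self.genotypes.copy())


@dataclass(frozen=True)
class NuclearFamily:
    father_id: str
    mother_id: str
    children: tuple[str, ...]


@dataclass
class Pedigree:
    """A validated, zero-loop extended pedigree."""

    pedigree_id: str
    members: dict[str, Individual] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        for ind in self.members.values():
            half = (ind.father_id == FOUNDER) != (ind.mother_id == FOUNDER)
            if half:
                raise StructureError(
                    f"pedigree {self.pedigree_id}: individual {ind.individual_id} "
                    "has exactly one specified parent (both or neither required)"
                )
            if not ind.is_founder:
                for pid, want in ((ind.father_id, Sex.MALE), (ind.mother_id, Sex.FEMALE)):
                    parent = self.members.get(pid)
                    if parent is None:
                        raise StructureError(
                            f"pedigree {self.pedigree_id}: parent {pid} of "
                            f"{ind.individual_id} is not a pedigree member"
                        )
                    if parent.sex != want:
                        role = "father" if want == Sex.MALE else "mother"
                        raise StructureError(
                            f"pedigree {self.pedigree_id}: {role} {pid} of "
                            f"{ind.individual_id} has wrong sex"
                        )
        n_markers = {ind.genotypes.shape[0] for ind in self.members.values()}
        if len(n_markers) > 1:
            raise StructureError(
                f"pedigree {self.pedigree_id}: inconsistent genotype vector lengths"
            )
        self._check_acyclic()
        self._check_zero_loop()

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.members)
        for ind in self.members.values():
            if not ind.is_founder:
                g.add_edge(ind.father_id, ind.individual_id)
                g.add_edge(ind.mother_id, ind.individual_id)
        if not nx.is_directed_acyclic_graph(g):
            raise StructureError(
                f"pedigree {self.pedigree_id}: ancestry contains a cycle"
            )

    def _check_zero_loop(self) -> None:
        # Bipartite membership graph: individuals <-> nuclear families. The
        # pedigree is zero-loop iff this graph is a forest; consanguineous
        # marriages (and marriage loops generally) create cycles in it.
        g = nx.Graph()
        g.add_nodes_from(self.members)
        for fam in self.nuclear_families():
            node = ("fam", fam.father_id, fam.mother_id)
            for member in (fam.father_id, fam.mother_id, *fam.children):
                g.add_edge(node, member)
        if g.number_of_nodes() and not nx.is_forest(g):
            raise UnsupportedPedigreeError(
                f"pedigree {self.pedigree_id}: marriage graph contains a loop "
                "(loop pedigrees are not supported by the peeling engine)"
            )

    def nuclear_families(self) -> list[NuclearFamily]:
        """Partition of non-founders into sibships keyed by parent pair."""
        fams: dict[tuple[str, str], list[str]] = {}
        for ind in self.members.values():
            if not ind.is_founder:
                fams.setdefault((ind.father_id, ind.mother_id), []).append(
                    ind.individual_id
                )
        return [
            NuclearFamily(f, m, tuple(kids)) for (f, m), kids in fams.items()
        ]

    # -- convenience -------------------------------------------------------

    @property
    def n_markers(self) -> int:
        first = next(iter(self.members.values()))
        return first.genotypes.shape[0]

    def genotype_matrix(self) -> np.ndarray:
        """``(n_members, n_markers, 2)`` allele-code array in member order."""
        return np.stack([ind.genotypes for ind in self.members.values()])

    def founders(self) -> list[Individual]:
        return [i for i in self.members.values() if i.is_founder]

    def copy(self) -> "Pedigree":
        return Pedigree(
            self.pedigree_id,
            {iid: ind.copy() for iid, ind in self.members.items()},
        )

    def __len__(self) -> int:
        return len(self.members)


class MarkerMap:
    """Ordered biallelic SNP map.

    Thin wrapper over a :class:`pandas.DataFrame` with columns
    ``marker, chrom, cm, freq1, freq2`` (and optionally ``bp``).  Positions
    must be nondecreasing within a chromosome and the two allele frequencies
    must sum to one.
    """

    COLUMNS = ["marker", "chrom", "cm", "freq1", "freq2"]

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ParseError(f"marker map missing columns: {missing}")
        self.frame = frame.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        f = self.frame
        if f["marker"].duplicated().any():
            dup = f.loc[f["marker"].duplicated(), "marker"].iloc[0]
            raise ParseError(f"duplicate marker name {dup!r}")
        if (f["cm"] < 0).any():
            raise ParseError("negative cM position in marker map")
        for chrom, grp in f.groupby("chrom", sort=False):
            if not grp["cm"].is_monotonic_increasing:
                raise ParseError(
                    f"cM positions not nondecreasing on chromosome {chrom}"
                )
        freqs = f[["freq1", "freq2"]].to_numpy(float)
        if not ((freqs > 0) & (freqs < 1)).all():
            raise ParseError("allele frequencies must lie strictly in (0, 1)")
        if not np.allclose(freqs.sum(axis=1), 1.0, atol=1e-9):
            raise ParseError("allele frequencies must sum to 1 within 1e-9")

    # -- access ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def names(self) -> list[str]:
        return self.frame["marker"].tolist()

    def freq(self, marker_index: int) -> tuple[float, float]:
        row = self.frame.iloc[marker_index]
        return float(row["freq1"]), float(row["freq2"])

    def subset(self, indices) -> "MarkerMap":
        return MarkerMap(self.frame.iloc[list(indices)].reset_index(drop=True))

    def __eq__(self, other) -> bool:
        if not isinstance(other, MarkerMap):
            return NotImplemented
        return self.frame.reset_index(drop=True).equals(
            other.frame.reset_index(drop=True)
        )

    # -- I/O -----------------------------------------------------------------

    @classmethod
    def read_tsv(cls, path) -> "MarkerMap":
        frame = pd.read_csv(path, sep="\t")
        frame.columns = [c.strip().lower() for c in frame.columns]
        return cls(frame)

    def write_tsv(self, path) -> None:
        cols = list(self.COLUMNS)
        if "bp" in self.frame.columns:
            cols.append("bp")
        self.frame[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# LINKAGE I/O
# ---------------------------------------------------------------------------


def read_linkage(ped_path, map_path) -> tuple[list[Pedigree], MarkerMap]:
    """Read a pre-makeped LINKAGE PED file and a TSV marker map.

    PED rows are whitespace-delimited: family, individual, father, mother,
    sex (1/2), phenotype (0/1/2/3), then two allele columns per marker with
    0 denoting a missing call.  Returns validated pedigrees (in file order)
    and the map.
    """
    marker_map = MarkerMap.read_tsv(map_path)
    n_markers = len(marker_map)
    expected = 6 + 2 * n_markers

    raw: dict[str, dict[str, Individual]] = {}
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != expected:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {expected} fields "
                    f"(6 + 2×{n_markers} markers), got {len(fields)}"
                )
            fam, iid, fid, mid, sex_s, phen_s = fields[:6]
            try:
                sex = Sex(int(sex_s))
                phen = Phenotype(int(phen_s))
                alleles = np.array([int(a) for a in fields[6:]], dtype=np.int16)
            except ValueError as exc:
                raise ParseError(f"{ped_path}:{lineno}: {exc}") from None
            if (alleles < 0).any():
                raise ParseError(f"{ped_path}:{lineno}: negative allele code")
            members = raw.setdefault(fam, {})
            if iid in members:
                raise ParseError(
                    f"{ped_path}:{lineno}: duplicate individual {iid} in family {fam}"
                )
            members[iid] = Individual(
                iid, fid, mid, sex, phen, alleles.reshape(n_markers, 2)
            )
    pedigrees = [Pedigree(fam, members) for fam, members in raw.items()]
    return pedigrees, marker_map


def write_linkage(pedigrees, ped_path) -> None:
    """Write pedigrees back to the same pre-makeped dialect, bit-stably."""
    with open(ped_path, "w") as fh:
        for ped in pedigrees:
            for ind in ped.members.values():
                alleles = " ".join(str(a) for a in ind.genotypes.ravel())
                fh.write(
                    f"{ped.pedigree_id} {ind.individual_id} {ind.father_id} "
                    f"{ind.mother_id} {int(ind.sex)} {int(ind.phenotype)} "
                    f"{alleles}\n"
                )


# ---------------------------------------------------------------------------
# Phenotype recoding and summaries
# ---------------------------------------------------------------------------


def recode_phenotypes(pedigree: Pedigree, trait: Trait | str) -> Pedigree:
    """Return a copy with binary affection status for the given trait.

    ASD is affected under both traits; BAP is unaffected under ``ASD`` and
    affected under ``ASD_BAP``; unknown phenotypes stay unknown (never
    imputed).  Genotypes and structure are untouched, and the operation is
    idempotent.
    """
    trait = Trait(trait)
    table = _RECODE[trait]
    out = pedigree.copy()
    for ind in out.members.values():
        ind.affection = table[ind.phenotype]
    return out


def pedigree_summary(pedigrees) -> pd.DataFrame:
    """Per-pedigree counts of cases and coverage, with an aggregate row.

    Columns: members, ASD, BAP, ASD+BAP, genotyped, phenotyped and the BAP
    prevalence among phenotyped members (NaN when nothing is phenotyped).
    The final ``__aggregate__`` row carries totals, and the frame's ``attrs``
    hold mean/sd/min/max of the ASD count across pedigrees.
    """
    pedigrees = list(pedigrees)
    if not pedigrees:
        raise ValueError("pedigree_summary requires at least one pedigree")
    rows = []
    for ped in pedigrees:
        phen = [i.phenotype for i in ped.members.values()]
        n_asd = sum(p == Phenotype.ASD for p in phen)
        n_bap = sum(p == Phenotype.BAP for p in phen)
        n_phen = sum(p != Phenotype.UNKNOWN for p in phen)
        n_geno = sum(
            (ind.genotypes > 0).any() for ind in ped.members.values()
        )
        rows.append(
            {
                "pedigree": ped.pedigree_id,
                "members": len(ped),
                "asd": n_asd,
                "bap": n_bap,
                "asd_bap": n_asd + n_bap,
                "genotyped": n_geno,
                "phenotyped": n_phen,
                "bap_prevalence": (n_bap / n_phen) if n_phen else np.nan,
            }
        )
    frame = pd.DataFrame(rows)
    total_phen = int(frame["phenotyped"].sum())
    total_bap = int(frame["bap"].sum())
    agg = {
        "pedigree": "__aggregate__",
        "members": int(frame["members"].sum()),
        "asd": int(frame["asd"].sum()),
        "bap": total_bap,
        "asd_bap": int(frame["asd_bap"].sum()),
        "genotyped": int(frame["genotyped"].sum()),
        "phenotyped": total_phen,
        "bap_prevalence": (total_bap / total_phen) if total_phen else np.nan,
    }
    out = pd.concat([frame, pd.DataFrame([agg])], ignore_index=True)
    asd = frame["asd"]
    out.attrs["asd_mean"] = float(asd.mean())
    out.attrs["asd_sd"] = float(asd.std(ddof=1)) if len(asd) > 1 else 0.0
    out.attrs["asd_min"] = int(asd.min())
    out.attrs["asd_max"] = int(asd.max())
    return out
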