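"""Genotype quality control for pedigree SNP data.

The cleaning protocol runs in a fixed order: (1) marker and individual
missingness filters, (2) Mendelian-inconsistency screening — markers with an
excess family-incident rate are dropped, remaining incidents are repaired by
setting the offending nuclear family's genotypes to missing at that SNP,
(3) a founder Hardy–Weinberg exact-test filter, and (4) greedy LD thinning of
the map on founder genotype correlations (r²).

Individuals failing the missingness filter are reported as dropped but kept
in the pedigree structure with all genotypes set to missing: removing a
connecting member would change the pedigree graph, whereas blanking their
genotypes only removes their marker information.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .pedigree import MarkerMap, NuclearFamily, Pedigree

__all__ = [
    "QcConfig",
    "QcReport",
    "DropReason",
    "missingness_by_marker",
    "missingness_by_individual",
    "mendel_check",
    "mendel_repair",
    "hwe_exact",
    "founder_genotype_counts",
    "ld_thin",
    "run_qc",
]


class DropReason(str, enum.Enum):
    MISSINGNESS = "MISSINGNESS"
    MENDEL_RATE = "MENDEL_RATE"
    HWE = "HWE"
    LD = "LD"
    MONOMORPHIC = "MONOMORPHIC"


@dataclass
class QcConfig:
    marker_missingness_max: float = 0.05
    individual_missingness_max: float = 0.05
    mendel_marker_rate_max: float = 0.05
    hwe_p_min: float = 1e-4
    ld_r2_max: float = 0.20
    ld_window: int = 50

    def __post_init__(self) -> None:
        for name in (
            "marker_missingness_max",
            "individual_missingness_max",
            "mendel_marker_rate_max",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not 0.0 < self.hwe_p_min < 1.0:
            raise ValueError(f"hwe_p_min must be in (0,1), got {self.hwe_p_min}")
        if not 0.0 < self.ld_r2_max <= 1.0:
            raise ValueError(f"ld_r2_max must be in (0,1], got {self.ld_r2_max}")
        if self.ld_window < 1:
            raise ValueError("ld_window must be >= 1")


@dataclass
class QcReport:
    dropped_markers: list[tuple[str, DropReason]] = field(default_factory=list)
    dropped_individuals: list[tuple[str, str]] = field(default_factory=list)
    repaired_genotypes: int = 0
    surviving_map: MarkerMap | None = None

    def dropped_by(self, reason: DropReason) -> list[str]:
        return [m for m, r in self.dropped_markers if r == reason]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _genotyped_mask(ped: Pedigree) -> np.ndarray:
    """Per-member flag: has at least one non-missing call anywhere."""
    g = ped.genotype_matrix()
    return (g > 0).any(axis=(1, 2))


def _stack_genotypes(pedigrees) -> tuple[np.ndarray, np.ndarray]:
    """All genotypes (n_total, n_markers, 2) and the genotyped-member mask."""
    mats = [ped.genotype_matrix() for ped in pedigrees]
    masks = [_genotyped_mask(ped) for ped in pedigrees]
    return np.concatenate(mats), np.concatenate(masks)


def subset_markers(pedigrees, keep: np.ndarray) -> list[Pedigree]:
    """Copy pedigrees restricted to the marker indices in ``keep``."""
    out = []
    for ped in pedigrees:
        cp = ped.copy()
        for ind in cp.members.values():
            ind.genotypes = ind.genotypes[keep].copy()
        cp._peel_structure = None
        out.append(cp)
    return out


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------


def missingness_by_marker(pedigrees) -> np.ndarray:
    """Fraction of missing calls per marker, among genotyped individuals."""
    geno, mask = _stack_genotypes(pedigrees)
    if not mask.any():
        raise ValueError("no genotyped individuals in cohort")
    g = geno[mask]
    return (g == 0).any(axis=2).mean(axis=0)


def missingness_by_individual(pedigrees) -> dict[tuple[str, str], float]:
    """Missing-call fraction per genotyped individual, keyed (pedigree, id)."""
    out = {}
    for ped in pedigrees:
        mask = _genotyped_mask(ped)
        for flag, (iid, ind) in zip(mask, ped.members.items()):
            if flag:
                out[(ped.pedigree_id, iid)] = float(
                    (ind.genotypes == 0).any(axis=1).mean()
                )
    return out


# ---------------------------------------------------------------------------
# Mendelian consistency
# ---------------------------------------------------------------------------

_GENOTYPES = [(1, 1), (1, 2), (2, 2)]


def _possible_genotypes(pair) -> list[tuple[int, int]]:
    a, b = int(pair[0]), int(pair[1])
    if a == 0 or b == 0:
        return _GENOTYPES
    return [(min(a, b), max(a, b))]


def _transmission_possible(child, father, mother) -> bool:
    ca, cb = child
    for fa in father:
        for mo in mother:
            if (ca in fa and cb in mo) or (cb in fa and ca in mo):
                return True
    return False


def mendel_check(pedigree: Pedigree, marker_index: int) -> list[tuple[NuclearFamily, str]]:
    """Children incompatible with any transmission from their parents.

    Missing genotypes (child or parent) are compatible with anything they do
    not directly contradict; a typed child is an incident only when no
    genotype completion of the parents can transmit it.
    """
    incidents = []
    for fam in pedigree.nuclear_families():
        father_g = _possible_genotypes(
            pedigree.members[fam.father_id].genotypes[marker_index]
        )
        mother_g = _possible_genotypes(
            pedigree.members[fam.mother_id].genotypes[marker_index]
        )
        for child in fam.children:
            pair = pedigree.members[child].genotypes[marker_index]
            if pair[0] == 0 or pair[1] == 0:
                continue
            child_g = (min(pair), max(pair))
            if not _transmission_possible(child_g, father_g, mother_g):
                incidents.append((fam, child))
    return incidents


def _informative_families(pedigrees, marker_index: int) -> int:
    """Families with >= 1 typed parent and >= 1 typed child at the marker."""
    n = 0
    for ped in pedigrees:
        for fam in ped.nuclear_families():
            typed = lambda iid: (ped.members[iid].genotypes[marker_index] > 0).all()
            if (typed(fam.father_id) or typed(fam.mother_id)) and any(
                typed(c) for c in fam.children
            ):
                n += 1
    return n


def mendel_marker_rates(pedigrees, n_markers: int) -> np.ndarray:
    """Per-marker family-incident rate (incident families / informative)."""
    rates = np.zeros(n_markers)
    for j in range(n_markers):
        denom = _informative_families(pedigrees, j)
        if denom == 0:
            continue
        fams = set()
        for ped in pedigrees:
            for fam, _child in mendel_check(ped, j):
                fams.add((ped.pedigree_id, fam.father_id, fam.mother_id))
        rates[j] = len(fams) / denom
    return rates


def mendel_repair(pedigrees, marker_index: int) -> int:
    """Blank the offending nuclear family's genotypes at the marker, in place.

    Parents and all children of any family with an incident are set to
    missing at this SNP; other families are untouched.  Returns the number
    of genotype cells blanked.  After repair, :func:`mendel_check` finds no
    incidents at the marker.
    """
    repaired = 0
    for ped in pedigrees:
        fams = {
            (fam.father_id, fam.mother_id): fam
            for fam, _ in mendel_check(ped, marker_index)
        }
        for fam in fams.values():
            for iid in (fam.father_id, fam.mother_id, *fam.children):
                g = ped.members[iid].genotypes
                if (g[marker_index] > 0).any():
                    repaired += 1
                g[marker_index] = 0
    return repaired


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided conditional exact test for Hardy–Weinberg proportions.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one
    (Wigginton-style exact test).
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        warnings.warn("HWE test on zero genotypes; returning p = 1")
        return 1.0
    n_a = 2 * n_aa + n_ab
    rare = min(n_a, 2 * n - n_a)
    # heterozygote count shares the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (
        gammaln(n + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
        + hets * np.log(2.0)
        + gammaln(rare + 1)
        + gammaln(2 * n - rare + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    observed = probs[np.searchsorted(hets, n_ab)]
    return float(probs[probs <= observed * (1.0 + 1e-12)].sum())


def founder_genotype_counts(pedigrees, marker_index: int) -> tuple[int, int, int]:
    """(n_11, n_12, n_22) among typed founders."""
    n = [0, 0, 0]
    for ped in pedigrees:
        for ind in ped.founders():
            pair = ind.genotypes[marker_index]
            if pair[0] > 0 and pair[1] > 0:
                n[int(pair[0]) + int(pair[1]) - 2] += 1
    return tuple(n)


# ---------------------------------------------------------------------------
# LD thinning
# ---------------------------------------------------------------------------


def _founder_dosage(pedigrees) -> np.ndarray:
    """(n_founders, n_markers) allele-1 dosage matrix, NaN for missing."""
    rows = []
    for ped in pedigrees:
        for ind in ped.founders():
            g = ind.genotypes
            dose = (g == 1).sum(axis=1).astype(float)
            dose[(g == 0).any(axis=1)] = np.nan
            rows.append(dose)
    return np.array(rows)


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared composite genotypic correlation on complete pairs."""
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        return 0.0
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        return 0.0
    return float(np.corrcoef(xs, ys)[0, 1] ** 2)


def ld_thin(
    pedigrees, marker_map: MarkerMap, config: QcConfig | None = None
) -> tuple[np.ndarray, list[tuple[str, DropReason]]]:
    """Greedy map-order LD pruning on founder genotype correlations.

    Within each chromosome a candidate marker is kept only if its r² with
    every already-kept marker inside the trailing window (``ld_window``
    markers of the input map) does not exceed ``ld_r2_max``.  Windows never
    span chromosomes.  Monomorphic founders exclude a marker outright.
    Returns the boolean keep mask and the (marker, reason) drop list.
    """
    config = config or QcConfig()
    dosage = _founder_dosage(pedigrees)
    names = marker_map.names
    chroms = marker_map.frame["chrom"].to_numpy()
    keep = np.zeros(len(marker_map), dtype=bool)
    dropped: list[tuple[str, DropReason]] = []
    for chrom in pd_unique(chroms):
        idx = np.nonzero(chroms == chrom)[0]
        kept_here: list[int] = []
        for i in idx:
            col = dosage[:, i]
            if np.all(np.isnan(col)) or np.nanstd(col) == 0:
                dropped.append((names[i], DropReason.MONOMORPHIC))
                continue
            window = [j for j in kept_here if i - j < config.ld_window]
            if all(_r2(dosage[:, j], col) <= config.ld_r2_max for j in window):
                keep[i] = True
                kept_here.append(i)
            else:
                dropped.append((names[i], DropReason.LD))
    return keep, dropped


def pd_unique(values):
    """Order-preserving unique."""
    seen, out = set(), []
    for v in values:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def run_qc(
    pedigrees, marker_map: MarkerMap, config: QcConfig | None = None
) -> tuple[list[Pedigree], MarkerMap, QcReport]:
    """Full cleaning pipeline: missingness → Mendel → HWE → LD thinning.

    Returns cleaned copies of the pedigrees (restricted to the surviving
    map), the thinned map, and a report of every drop with its reason.
    Re-running the pipeline on its own output is a no-op.
    """
    config = config or QcConfig()
    report = QcReport()
    pedigrees = [ped.copy() for ped in pedigrees]
    names = marker_map.names

    # 1a. marker missingness (strict exceedance drops)
    miss = missingness_by_marker(pedigrees)
    keep = miss <= config.marker_missingness_max
    for j in np.nonzero(~keep)[0]:
        report.dropped_markers.append((names[j], DropReason.MISSINGNESS))
    pedigrees = subset_markers(pedigrees, keep)
    marker_map = marker_map.subset(np.nonzero(keep)[0])
    names = marker_map.names

    # 1b. individual missingness over the post-drop map; failing individuals
    # keep their place in the structure but lose all genotype calls
    for (pid, iid), frac in missingness_by_individual(pedigrees).items():
        if frac > config.individual_missingness_max:
            report.dropped_individuals.append((pid, iid))
            ped = next(p for p in pedigrees if p.pedigree_id == pid)
            ped.members[iid].genotypes[:] = 0

    # 2. Mendel errors: drop high-rate markers, repair the rest within family
    rates = mendel_marker_rates(pedigrees, len(marker_map))
    keep = rates <= config.mendel_marker_rate_max
    for j in np.nonzero(~keep)[0]:
        report.dropped_markers.append((names[j], DropReason.MENDEL_RATE))
    pedigrees = subset_markers(pedigrees, keep)
    marker_map = marker_map.subset(np.nonzero(keep)[0])
    names = marker_map.names
    for j in range(len(marker_map)):
        report.repaired_genotypes += mendel_repair(pedigrees, j)

    # 3. founder HWE filter
    keep = np.ones(len(marker_map), dtype=bool)
    for j in range(len(marker_map)):
        counts = founder_genotype_counts(pedigrees, j)
        if sum(counts) and hwe_exact(*counts) < config.hwe_p_min:
            keep[j] = False
            report.dropped_markers.append((names[j], DropReason.HWE))
    pedigrees = subset_markers(pedigrees, keep)
    marker_map = marker_map.subset(np.nonzero(keep)[0])

    # 4. LD thinning
    keep, dropped = ld_thin(pedigrees, marker_map, config)
    report.dropped_markers.extend(dropped)
    pedigrees = subset_markers(pedigrees, keep)
    marker_map = marker_map.subset(np.nonzero(keep)[0])

    report.surviving_map = marker_map
    return pedigrees, marker_map, report
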