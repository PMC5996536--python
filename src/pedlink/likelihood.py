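"""Exact trait–marker two-locus pedigree likelihoods.

The joint state of one individual is an ordered pair of haplotypes, each
haplotype carrying a trait allele (D or d) and a biallelic marker allele
(1 or 2): 16 states per individual, with the paternally derived haplotype
first.  The pedigree likelihood sums, over all joint assignments, the product
of founder haplotype priors (Hardy–Weinberg and linkage equilibrium),
transmission probabilities with recombination fraction θ, penetrance terms
for the binary affection status, and marker-genotype compatibility
indicators.

The sum is evaluated exactly by Elston–Stewart peeling: nuclear families are
peeled from the periphery of the (zero-loop) pedigree inward, passing a
16-state message through each connecting individual.  Peeling is vectorised
over a batch of trait models and a batch of θ values simultaneously, which is
what makes grid integration in the PPL engine affordable.  Per-family
rescaling with an accumulated log correction keeps big pedigrees from
underflowing, so likelihoods are reported on the log scale internally.

A direct enumeration of the joint state space
(:func:`pedigree_likelihood_enumerate`) is provided as an independent,
structurally different check of the peeling engine; it is exponential in
pedigree size and meant for small pedigrees only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .pedigree import Affection, MarkerMap, Pedigree, UnsupportedPedigreeError

__all__ = [
    "TraitModel",
    "haldane_theta",
    "haldane_cm",
    "pedigree_likelihood",
    "log_pedigree_likelihood",
    "pedigree_likelihood_enumerate",
    "lod",
    "admixture_likelihood",
    "batched_log_likelihood",
]

THETA_UNLINKED = 0.5


@dataclass(frozen=True)
class TraitModel:
    """Single-locus diallelic trait model.

    ``p`` is the disease-allele (D) frequency; ``f1, f2, f3`` are the
    penetrances for genotypes DD, Dd and dd.  The ordering constraint
    ``f1 >= f2 >= f3`` is enforced; ``f3 > 0`` allows phenocopies.
    """

    p: float
    f1: float
    f2: float
    f3: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"disease allele frequency must be in (0,1), got {self.p}")
        for f in (self.f1, self.f2, self.f3):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"penetrance {f} outside [0,1]")
        if not self.f1 >= self.f2 >= self.f3:
            raise ValueError(
                f"penetrances must satisfy f1 >= f2 >= f3, got "
                f"({self.f1}, {self.f2}, {self.f3})"
            )

    @property
    def penetrances(self) -> np.ndarray:
        return np.array([self.f1, self.f2, self.f3])


def haldane_theta(distance_cm: float) -> float:
    """Map cM distance to recombination fraction (Haldane, no interference)."""
    if distance_cm < 0:
        raise ValueError(f"genetic distance must be nonnegative, got {distance_cm}")
    return 0.5 * (1.0 - math.exp(-2.0 * distance_cm / 100.0))

def haldane_cm(theta: float) -> float:
    """Inverse Haldane map function: θ in [0, 0.5) to distance in cM."""
    if not 0.0 <= theta < 0.5:
        raise ValueError(f"theta must be in [0, 0.5), got {theta}")
    return -50.0 * math.log(1.0 - 2.0 * theta)


# ---------------------------------------------------------------------------
# State space: haplotype h = 2*trait + marker (trait 0=D, 1=d; marker 0/1),
# ordered genotype g = 4*paternal_hap + maternal_hap.
# ---------------------------------------------------------------------------

_PAT = np.arange(16) // 4
_MAT = np.arange(16) % 4
_TRAIT_OF_HAP = np.arange(4) // 2   # 0 = D
_MARK_OF_HAP = np.arange(4) % 2
_N_D = (_TRAIT_OF_HAP[_PAT] == 0).astype(int) + (_TRAIT_OF_HAP[_MAT] == 0).astype(int)
_MARKER_PAIR = np.stack(
    [
        np.minimum(_MARK_OF_HAP[_PAT], _MARK_OF_HAP[_MAT]) + 1,
        np.maximum(_MARK_OF_HAP[_PAT], _MARK_OF_HAP[_MAT]) + 1,
    ],
    axis=1,
)


def _gamete_probs(theta: float) -> np.ndarray:
    """(16, 4): probability that genotype g transmits haplotype h."""
    out = np.zeros((16, 4))
    for g in range(16):
        hp, hm = _PAT[g], _MAT[g]
        tp, mp = _TRAIT_OF_HAP[hp], _MARK_OF_HAP[hp]
        tm, mm = _TRAIT_OF_HAP[hm], _MARK_OF_HAP[hm]
        # parental gametes keep (trait, marker) from one haplotype;
        # recombinants mix the trait allele of one with the marker of the other
        for (t, m), pr in (
            ((tp, mp), (1 - theta) / 2),
            ((tm, mm), (1 - theta) / 2),
            ((tp, mm), theta / 2),
            ((tm, mp), theta / 2),
        ):
            out[g, 2 * t + m] += pr
    return out


def transmission_tensor(thetas) -> np.ndarray:
    """(T, 16, 16, 16) array: P(child g | father g_f, mother g_m; θ)."""
    thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
    if ((thetas < 0) | (thetas > 0.5)).any():
        raise ValueError("theta must lie in [0, 0.5]")
    out = np.empty((len(thetas), 16, 16, 16))
    for k, th in enumerate(thetas):
        gam = _gamete_probs(th)  # (16, 4)
        # child's paternal hap comes from the father, maternal from the mother
        out[k] = (
            gam[:, _PAT].T[:, :, np.newaxis] * gam[:, _MAT].T[:, np.newaxis, :]
        )
    return out


def _founder_prior(model: TraitModel, freq1: float) -> np.ndarray:
    """(16,) HWE × linkage-equilibrium prior over ordered two-locus genotypes."""
    trait_freq = np.array([model.p, 1.0 - model.p])
    mark_freq = np.array([freq1, 1.0 - freq1])
    hap = trait_freq[_TRAIT_OF_HAP] * mark_freq[_MARK_OF_HAP]
    return hap[_PAT] * hap[_MAT]


def _penetrance_weight(model: TraitModel, affection: Affection) -> np.ndarray:
    """(16,) phenotype term: f for affected, 1-f for unaffected, 1 for unknown."""
    f = np.array([model.f3, model.f2, model.f1])[_N_D]
    if affection == Affection.AFFECTED:
        return f
    if affection == Affection.UNAFFECTED:
        return 1.0 - f
    return np.ones(16)


def _marker_compat(pair: np.ndarray) -> np.ndarray:
    """(16,) indicator of compatibility with an observed unordered allele pair."""
    a, b = int(pair[0]), int(pair[1])
    if a == 0 or b == 0:  # missing call compatible with everything
        return np.ones(16)
    lo, hi = min(a, b), max(a, b)
    return ((_MARKER_PAIR[:, 0] == lo) & (_MARKER_PAIR[:, 1] == hi)).astype(float)


# ---------------------------------------------------------------------------
# Peeling
# ---------------------------------------------------------------------------


@dataclass
class _PeelStep:
    family: int          # index into the family list
    pivot: int | None    # member index receiving the message, None = terminal


class _Structure:
    """Peel schedule for a zero-loop pedigree, cached on the Pedigree."""

    def __init__(self, ped: Pedigree):
        self.ids = list(ped.members)
        index = {iid: k for k, iid in enumerate(self.ids)}
        self.founder = np.array([ped.members[i].is_founder for i in self.ids])
        self.families = [
            (index[f.father_id], index[f.mother_id], [index[c] for c in f.children])
            for f in ped.nuclear_families()
        ]
        self.schedule = self._schedule()

    def _schedule(self) -> list[_PeelStep]:
        membership: dict[int, set[int]] = {}
        for fi, (fa, mo, kids) in enumerate(self.families):
            for m in (fa, mo, *kids):
                membership.setdefault(m, set()).add(fi)
        active = set(range(len(self.families)))
        steps: list[_PeelStep] = []
        while active:
            for fi in sorted(active):
                fa, mo, kids = self.families[fi]
                shared = [
                    m
                    for m in (fa, mo, *kids)
                    if len(membership[m] & active) > 1
                ]
                if len(shared) <= 1:
                    steps.append(_PeelStep(fi, shared[0] if shared else None))
                    active.discard(fi)
                    break
            else:  # pragma: no cover - guarded by zero-loop validation
                raise UnsupportedPedigreeError(
                    "no peelable peripheral family found (loop pedigree?)"
                )
        return steps


def _get_structure(ped: Pedigree) -> _Structure:
    cached = getattr(ped, "_peel_structure", None)
    if cached is None:
        cached = _Structure(ped)
        ped._peel_structure = cached
    return cached


def _weights(
    ped: Pedigree, struct: _Structure, marker_index: int, models, freq1: float
) -> np.ndarray:
    """(n_members, M, 16) per-individual state weights for each trait model."""
    geno = ped.genotype_matrix()[:, marker_index, :]
    M = len(models)
    out = np.empty((len(struct.ids), M, 16))
    for k, iid in enumerate(struct.ids):
        ind = ped.members[iid]
        if ind.affection is None:
            raise ValueError(
                f"individual {iid} has no binary affection status; "
                "run recode_phenotypes first"
            )
        compat = _marker_compat(geno[k])
        for m, model in enumerate(models):
            w = _penetrance_weight(model, ind.affection) * compat
            if struct.founder[k]:
                w = w * _founder_prior(model, freq1)
            out[k, m] = w
    return out


def batched_log_likelihood(
    pedigree: Pedigree,
    marker_index: int,
    models,
    thetas,
    marker_map: MarkerMap,
) -> np.ndarray:
    """Log-likelihood array of shape ``(n_models, n_thetas)``.

    One peel of the pedigree evaluates every (trait model, θ) combination;
    models vary the per-individual state weights, θ varies the transmission
    tensor, and both batch dimensions ride through the einsum contractions.
    """
    struct = _get_structure(pedigree)
    models = list(models)
    thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
    freq1 = marker_map.freq(marker_index)[0]
    M, T = len(models), len(thetas)

    trans = transmission_tensor(thetas)  # (T, 16, 16, 16)
    base = _weights(pedigree, struct, marker_index, models, freq1)
    # working weights carry both batch axes: (M, T, 16) per member
    w = [np.broadcast_to(base[k][:, None, :], (M, T, 16)).copy() for k in range(len(struct.ids))]
    logscale = np.zeros((M, T))
    in_family = set()
    for fa, mo, kids in struct.families:
        in_family.update((fa, mo, *kids))

    def child_message(c: int) -> np.ndarray:
        # (M, T, 16f, 16m): child's weight summed against transmission
        return np.einsum("mtc,tcfg->mtfg", w[c], trans, optimize=True)

    for step in struct.schedule:
        fa, mo, kids = struct.families[step.family]
        pivot = step.pivot
        if pivot in kids:
            others = [c for c in kids if c != pivot]
            joint = np.einsum("mtf,mtg->mtfg", w[fa], w[mo])
            for c in others:
                joint = joint * child_message(c)
            msg = np.einsum("mtfg,tcfg->mtc", joint, trans, optimize=True)
            w[pivot] = w[pivot] * msg
        else:
            prod = child_message(kids[0])
            for c in kids[1:]:
                prod = prod * child_message(c)
            if pivot == fa:
                msg = np.einsum("mtfg,mtg->mtf", prod, w[mo], optimize=True)
                w[fa] = w[fa] * msg
            elif pivot == mo:
                msg = np.einsum("mtfg,mtf->mtg", prod, w[fa], optimize=True)
                w[mo] = w[mo] * msg
            else:  # terminal family of a component: collapse to a scalar
                total = np.einsum("mtfg,mtf,mtg->mt", prod, w[fa], w[mo], optimize=True)
                with np.errstate(divide="ignore"):
                    logscale += np.log(total)
                continue
        # rescale the pivot's weight to keep the recursion in range
        s = w[pivot].max(axis=-1, keepdims=True)
        safe = np.where(s > 0, s, 1.0)
        w[pivot] = w[pivot] / safe
        with np.errstate(divide="ignore"):
            logscale += np.log(safe[..., 0])
        logscale[(s[..., 0] == 0)] = -np.inf

    # singletons and isolated founders never touched by any family
    for k in range(len(struct.ids)):
        if k not in in_family:
            with np.errstate(divide="ignore"):
                logscale += np.log(w[k].sum(axis=-1))
    return logscale


def log_pedigree_likelihood(
    pedigree: Pedigree,
    marker_index: int,
    theta: float,
    model: TraitModel,
    marker_map: MarkerMap,
) -> float:
    if not 0.0 <= theta <= 0.5:
        raise ValueError(f"theta must be in [0, 0.5], got {theta}")
    return float(
        batched_log_likelihood(pedigree, marker_index, [model], [theta], marker_map)[
            0, 0
        ]
    )


def pedigree_likelihood(
    pedigree: Pedigree,
    marker_index: int,
    theta: float,
    model: TraitModel,
    marker_map: MarkerMap,
) -> float:
    """Exact two-locus pedigree likelihood L(θ) at one marker."""
    return math.exp(log_pedigree_likelihood(pedigree, marker_index, theta, model, marker_map))


def lod(
    pedigree: Pedigree,
    marker_index: int,
    theta: float,
    model: TraitModel,
    marker_map: MarkerMap,
) -> float:
    """Two-point LOD score log10[L(θ)/L(0.5)] at a fixed trait model."""
    ll = batched_log_likelihood(
        pedigree, marker_index, [model], [theta, THETA_UNLINKED], marker_map
    )[0]
    if not np.isfinite(ll[1]):
        raise ValueError("null likelihood L(0.5) is zero; data inconsistent")
    return float((ll[0] - ll[1]) / math.log(10.0))


def admixture_likelihood(
    pedigree: Pedigree,
    marker_index: int,
    theta: float,
    alpha: float,
    model: TraitModel,
    marker_map: MarkerMap,
) -> float:
    """Smith admixture likelihood α·L(θ) + (1−α)·L(0.5).

    α is the proportion of linked pedigrees; α = 1 recovers the homogeneity
    likelihood.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    ll = batched_log_likelihood(
        pedigree, marker_index, [model], [theta, THETA_UNLINKED], marker_map
    )[0]
    return float(alpha * np.exp(ll[0]) + (1.0 - alpha) * np.exp(ll[1]))


# ---------------------------------------------------------------------------
# Independent enumeration check
# ---------------------------------------------------------------------------


def pedigree_likelihood_enumerate(
    pedigree: Pedigree,
    marker_index: int,
    theta: float,
    model: TraitModel,
    marker_map: MarkerMap,
    max_states: int = 8_000_000,
) -> float:
    """Likelihood by direct summation over every joint genotype assignment.

    Individuals are restricted to states compatible with their observed
    marker genotype (16 states when untyped), and the full cartesian product
    of those state lists is materialised.  Exponential in pedigree size —
    a cross-check for the peeling engine, not an analysis path.
    """
    struct = _Structure(pedigree)
    ids = struct.ids
    index = {iid: k for k, iid in enumerate(ids)}
    freq1 = marker_map.freq(marker_index)[0]
    geno = pedigree.genotype_matrix()[:, marker_index, :]
    trans = transmission_tensor([theta])[0]

    weights = []
    cands = []
    for k, iid in enumerate(ids):
        ind = pedigree.members[iid]
        if ind.affection is None:
            raise ValueError("run recode_phenotypes first")
        w = _penetrance_weight(model, ind.affection) * _marker_compat(geno[k])
        if ind.is_founder:
            w = w * _founder_prior(model, freq1)
        nz = np.nonzero(_marker_compat(geno[k]))[0]
        weights.append(w)
        cands.append(nz)

    total = 1
    for c in cands:
        total *= len(c)
    if total > max_states:
        raise ValueError(
            f"joint state space {total} exceeds max_states={max_states}"
        )

    grids = np.meshgrid(*cands, indexing="ij")
    states = np.stack([g.ravel() for g in grids])  # (n_members, total)
    prob = np.ones(total)
    for k in range(len(ids)):
        prob *= weights[k][states[k]]
    for iid in ids:
        ind = pedigree.members[iid]
        if not ind.is_founder:
            c, f, m = index[iid], index[ind.father_id], index[ind.mother_id]
            prob *= trans[states[c], states[f], states[m]]
    return float(prob.sum())
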