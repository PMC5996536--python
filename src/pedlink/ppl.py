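"""Posterior probability of linkage (PPL) from integrated Bayes ratios.

The Bayes ratio (BR) at a genomic position is the likelihood ratio of
"linked" versus "unlinked" with every trait parameter integrated out over
essentially uniform priors: the recombination fraction θ over the linked
range, Smith's admixture proportion α of linked pedigrees, the disease
allele frequency p, and the penetrance vector (f1, f2, f3) constrained to
f1 ≥ f2 ≥ f3.  The BR maps onto the probability scale through the prior
probability of linkage π (default 2%):

    PPL = π·BR / (π·BR + 1 − π)

so BR = 1 returns the prior, and PPL > π (resp. < π) is evidence for
(against) a trait gene at the position.  No multiple-testing adjustment is
ever applied; the PPL is a measure of evidence, not a decision rule.

Evidence accumulates across pedigrees in two modes.  Under SEQUENTIAL
updating each pedigree's BR integrates the trait parameters separately and
the per-pedigree BRs multiply — appropriate under locus/model heterogeneity,
and also how evidence combines across independently collected cohorts.
Under POOLED the parameters are integrated once jointly across all pedigrees
— appropriate when pedigrees share one trait model.  All products are
accumulated in the log domain and exponentiated only for reporting.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit, logsumexp

from .likelihood import THETA_UNLINKED, TraitModel, batched_log_likelihood
from .pedigree import MarkerMap, Pedigree

__all__ = [
    "Mode",
    "PplConfig",
    "ScanResult",
    "penetrance_lattice",
    "integrate_br",
    "ppl_from_br",
    "sequential_update",
    "pooled_br",
    "genome_scan",
    "fraction_against",
]


class Mode(str, enum.Enum):
    POOLED = "POOLED"
    SEQUENTIAL = "SEQUENTIAL"


class ConfigError(ValueError):
    """Invalid or empty integration grid."""


def penetrance_lattice(step: float = 0.05) -> list[tuple[float, float, float]]:
    """All (f1, f2, f3) triples on a ``step`` lattice with f1 ≥ f2 ≥ f3."""
    k = round(1.0 / step)
    vals = [i / k for i in range(k + 1)]
    return [
        (f1, f2, f3)
        for f1, f2, f3 in itertools.product(vals, repeat=3)
        if f1 >= f2 >= f3
    ]


@dataclass
class PplConfig:
    """Integration grids and prior for the PPL.

    The defaults follow the analysis convention: uniform weights on every
    grid after the penetrance ordering constraint, and π = 2% (one disease
    gene genome-wide — conservative under locus heterogeneity).
    ``coarse()`` provides a reduced grid with the same structure for
    genome-wide scans and simulation studies, where the full 0.05-step
    penetrance lattice would be needlessly slow.
    """

    prior_pi: float = 0.02
    alpha_grid: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2))
    p_grid: tuple[float, ...] = (0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.3, 0.5)
    penetrance_grid: list[tuple[float, float, float]] = field(
        default_factory=penetrance_lattice
    )
    theta_grid: tuple[float, ...] = (
        0.0, 0.01, 0.02, 0.03, 0.04, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45,
    )
    theta_weights: tuple[float, ...] | None = None  # None = uniform
    mode: Mode = Mode.SEQUENTIAL

    def __post_init__(self) -> None:
        self.mode = Mode(self.mode)
        if not 0.0 < self.prior_pi < 1.0:
            raise ConfigError(f"prior_pi must be in (0,1), got {self.prior_pi}")
        self.penetrance_grid = [
            t for t in self.penetrance_grid if t[0] >= t[1] >= t[2]
        ]
        for name, grid in (
            ("alpha_grid", self.alpha_grid),
            ("p_grid", self.p_grid),
            ("penetrance_grid", self.penetrance_grid),
            ("theta_grid", self.theta_grid),
        ):
            if len(grid) == 0:
                raise ConfigError(f"{name} is empty (after constraint filtering)")
        if any(not 0.0 < a <= 1.0 for a in self.alpha_grid):
            raise ConfigError("alpha values must lie in (0, 1]")
        if any(not 0.0 <= t < 0.5 for t in self.theta_grid):
            raise ConfigError("theta grid values must lie in [0, 0.5)")
        if self.theta_weights is not None:
            w = np.asarray(self.theta_weights, float)
            if len(w) != len(self.theta_grid) or not np.isclose(w.sum(), 1.0):
                raise ConfigError("theta_weights must match theta_grid and sum to 1")

    @classmethod
    def coarse(cls, prior_pi: float = 0.02, mode: Mode = Mode.SEQUENTIAL) -> "PplConfig":
        """Reduced grids for genome scans (~100× fewer likelihood points)."""
        return cls(
            prior_pi=prior_pi,
            alpha_grid=(0.2, 0.4, 0.6, 0.8, 1.0),
            p_grid=(0.01, 0.1, 0.3),
            penetrance_grid=penetrance_lattice(0.25),
            theta_grid=(0.0, 0.05, 0.1, 0.2, 0.3, 0.4),
            mode=mode,
        )

    @property
    def trait_models(self) -> list[TraitModel]:
        return [
            TraitModel(p, *f)
            for p in self.p_grid
            for f in self.penetrance_grid
        ]

    @property
    def log_theta_weights(self) -> np.ndarray:
        if self.theta_weights is None:
            return np.full(len(self.theta_grid), -np.log(len(self.theta_grid)))
        return np.log(np.asarray(self.theta_weights, float))

    @property
    def grid_size(self) -> int:
        return (
            len(self.p_grid)
            * len(self.penetrance_grid)
            * len(self.theta_grid)
            * len(self.alpha_grid)
        )


# ---------------------------------------------------------------------------
# Per-pedigree grid evaluation
# ---------------------------------------------------------------------------


def _log_admixture_ratio_grid(
    pedigree: Pedigree,
    marker_index: int,
    config: PplConfig,
    marker_map: MarkerMap,
) -> np.ndarray:
    """``(M, T, A)`` log of [α·L(θ)/L(0.5) + (1 − α)] over the full grid.

    One batched peel per pedigree/marker evaluates every trait model and
    every θ (plus the θ = 0.5 reference); the α mixture is applied
    analytically on the resulting likelihood ratios.
    """
    models = config.trait_models
    thetas = list(config.theta_grid) + [THETA_UNLINKED]
    ll = batched_log_likelihood(pedigree, marker_index, models, thetas, marker_map)
    with np.errstate(invalid="ignore"):
        log_ratio = ll[:, :-1] - ll[:, -1:]  # (M, T)
    # grid points whose trait model makes the data impossible (L identically
    # zero at every theta) carry no linkage information: ratio := 1
    impossible = ~np.isfinite(ll[:, -1])
    log_ratio[impossible, :] = 0.0
    ratio = np.exp(log_ratio)
    alphas = np.asarray(config.alpha_grid, float)
    mix = alphas[None, None, :] * ratio[:, :, None] + (1.0 - alphas)[None, None, :]
    with np.errstate(divide="ignore"):
        return np.log(mix)


def _log_br_from_terms(log_terms: np.ndarray, config: PplConfig) -> float:
    """Weighted grid average of exp(log_terms), in the log domain."""
    M, T, A = log_terms.shape
    logw = (
        config.log_theta_weights[None, :, None]
        - np.log(M)
        - np.log(A)
    )
    return float(logsumexp(log_terms + logw))


def log_integrate_br(
    pedigree: Pedigree,
    marker_index: int,
    config: PplConfig,
    marker_map: MarkerMap,
) -> float:
    terms = _log_admixture_ratio_grid(pedigree, marker_index, config, marker_map)
    return _log_br_from_terms(terms, config)


def integrate_br(
    pedigree: Pedigree,
    marker_index: int,
    config: PplConfig,
    marker_map: MarkerMap,
) -> float:
    """Per-pedigree Bayes ratio with trait parameters integrated out."""
    return float(np.exp(log_integrate_br(pedigree, marker_index, config, marker_map)))


def ppl_from_br(br: float, prior_pi: float = 0.02) -> float:
    """Map a Bayes ratio onto the posterior probability scale.

    PPL = π·BR / (π·BR + 1 − π): equals π at BR = 1, is strictly increasing
    in BR, and tends to 1 as BR → ∞.
    """
    if not br > 0:
        raise ValueError(f"Bayes ratio must be positive, got {br}")
    if not 0.0 < prior_pi < 1.0:
        raise ValueError(f"prior_pi must be in (0,1), got {prior_pi}")
    return _ppl_from_log_br(np.log(br), prior_pi)


def _ppl_from_log_br(log_br: float, prior_pi: float) -> float:
    return float(expit(log_br + logit(prior_pi)))


def sequential_update(per_pedigree_brs, prior_pi: float = 0.02) -> float:
    """Bayesian sequential updating: multiply BRs, then transform via π.

    The inputs may be per-pedigree BRs within one cohort or combined BRs
    from independently analysed cohorts; the product is order-invariant.
    """
    brs = np.asarray(list(per_pedigree_brs), float)
    if brs.size == 0:
        raise ValueError("need at least one Bayes ratio")
    if (brs <= 0).any():
        raise ValueError("all Bayes ratios must be positive")
    return _ppl_from_log_br(np.log(brs).sum(), prior_pi)


def log_pooled_br(
    pedigrees, marker_index: int, config: PplConfig, marker_map: MarkerMap
) -> float:
    pedigrees = list(pedigrees)
    if not pedigrees:
        raise ValueError("need at least one pedigree")
    total = None
    for ped in pedigrees:
        terms = _log_admixture_ratio_grid(ped, marker_index, config, marker_map)
        total = terms if total is None else total + terms
    return _log_br_from_terms(total, config)


def pooled_br(
    pedigrees, marker_index: int, config: PplConfig, marker_map: MarkerMap
) -> float:
    """Bayes ratio integrating trait parameters jointly across pedigrees."""
    return float(np.exp(log_pooled_br(pedigrees, marker_index, config, marker_map)))


# ---------------------------------------------------------------------------
# Genome scan
# ---------------------------------------------------------------------------


@dataclass
class ScanResult:
    """PPL track across marker positions.

    ``frame`` has one row per (chromosome, marker) with columns ``chrom``,
    ``marker``, ``cm``, one ``log_br_<pedigree>`` column per pedigree (the
    per-pedigree integrated BR on the natural-log scale), ``log_br``
    (combined), ``br`` and ``ppl``.
    """

    frame: pd.DataFrame
    mode: Mode
    prior_pi: float
    grid_size: int | None = None

    @property
    def ppl(self) -> np.ndarray:
        return self.frame["ppl"].to_numpy()

    def pedigree_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c.startswith("log_br_")]

    def update(self, other: "ScanResult") -> "ScanResult":
        """Sequentially update with an independently analysed cohort.

        Positions are matched exactly on (chrom, marker, cm); any mismatch
        is an error, never an interpolation.  The combined BR is the product
        of the two cohorts' combined BRs, per position.
        """
        if abs(self.prior_pi - other.prior_pi) > 1e-12:
            raise ValueError("cannot combine scans with different priors")
        key = ["chrom", "marker", "cm"]
        a, b = self.frame, other.frame
        if len(a) != len(b) or not (
            a[key].reset_index(drop=True) == b[key].reset_index(drop=True)
        ).all().all():
            raise ValueError("scan position grids do not match exactly")
        ped_a = a[self.pedigree_columns()].reset_index(drop=True)
        ped_b = b[other.pedigree_columns()].reset_index(drop=True)
        ped_b = ped_b.rename(
            columns={c: c + "_b" for c in ped_b.columns if c in ped_a.columns}
        )
        log_br = a["log_br"].to_numpy() + b["log_br"].to_numpy()
        frame = pd.concat(
            [a[key].reset_index(drop=True), ped_a, ped_b], axis=1
        )
        frame["log_br"] = log_br
        frame["br"] = np.exp(log_br)
        frame["ppl"] = expit(log_br + logit(self.prior_pi))
        return ScanResult(frame, Mode.SEQUENTIAL, self.prior_pi, self.grid_size)

    def to_tsv(self, path) -> None:
        meta = f"# mode={self.mode.value} prior_pi={self.prior_pi!r}\n"
        with open(path, "w") as fh:
            fh.write(meta)
            self.frame.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "ScanResult":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError("scan TSV missing metadata header line")
            meta = dict(tok.split("=") for tok in header[1:].split())
            frame = pd.read_csv(fh, sep="\t")
        frame["chrom"] = frame["chrom"].astype(str)
        return cls(frame, Mode(meta["mode"]), float(meta["prior_pi"]))


def genome_scan(
    pedigrees, marker_map: MarkerMap, config: PplConfig | None = None
) -> ScanResult:
    """BR and PPL at every marker position for a recoded cohort.

    Positions are the marker cM positions (two-point evaluation).  Both the
    per-pedigree BRs and the combined BR of the configured mode are
    recorded, so a scan's per-pedigree table can later be merged with a
    second cohort via :meth:`ScanResult.update`.
    """
    config = config or PplConfig.coarse()
    pedigrees = list(pedigrees)
    if not pedigrees:
        raise ValueError("need at least one pedigree")
    n_markers = len(marker_map)
    for ped in pedigrees:
        if ped.n_markers != n_markers:
            raise ValueError(
                f"pedigree {ped.pedigree_id} carries {ped.n_markers} markers, "
                f"map has {n_markers}"
            )
    rows = []
    for j in range(n_markers):
        row: dict = {
            "chrom": str(marker_map.frame.at[j, "chrom"]),
            "marker": marker_map.frame.at[j, "marker"],
            "cm": float(marker_map.frame.at[j, "cm"]),
        }
        pooled_terms = None
        log_brs = []
        for ped in pedigrees:
            terms = _log_admixture_ratio_grid(ped, j, config, marker_map)
            log_br = _log_br_from_terms(terms, config)
            row[f"log_br_{ped.pedigree_id}"] = log_br
            log_brs.append(log_br)
            if config.mode == Mode.POOLED:
                pooled_terms = terms if pooled_terms is None else pooled_terms + terms
        if config.mode == Mode.POOLED:
            combined = _log_br_from_terms(pooled_terms, config)
        else:
            combined = float(np.sum(log_brs))
        row["log_br"] = combined
        row["br"] = float(np.exp(combined))
        row["ppl"] = _ppl_from_log_br(combined, config.prior_pi)
        rows.append(row)
    frame = pd.DataFrame(rows)
    return ScanResult(frame, config.mode, config.prior_pi, config.grid_size)


def fraction_against(scan: ScanResult, threshold: float | None = None) -> float:
    """Percentage of scanned positions with PPL ≤ threshold (default π).

    The comparison is inclusive: PPL exactly at the prior counts as evidence
    against linkage.
    """
    if len(scan.frame) == 0:
        raise ValueError("empty scan")
    thr = scan.prior_pi if threshold is None else threshold
    return float(100.0 * np.mean(scan.ppl <= thr + 1e-12))
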