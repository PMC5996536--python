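"""Model/Results front end for PPL linkage scans.

`LinkageScanModel` bundles a pedigree cohort, a marker map and the
integration configuration; `fit()` runs the genome scan and returns a
`LinkageScanResults` carrying the per-position Bayes ratios and PPLs,
peak calls, plotting and cross-cohort sequential updating.

    >>> model = LinkageScanModel(pedigrees, marker_map, trait="ASD")
    >>> res = model.fit()
    >>> print(res.summary())
    >>> res.call_peaks()
"""

from __future__ import annotations

from dataclasses import dataclass

from . import report
from .pedigree import MarkerMap, Pedigree, Trait, pedigree_summary, read_linkage, recode_phenotypes
from .ppl import Mode, PplConfig, ScanResult, fraction_against, genome_scan
from .qc import QcConfig, QcReport, run_qc


class LinkageScanModel:
    """Posterior-probability-of-linkage scan of a pedigree cohort.

    Parameters
    ----------
    pedigrees : sequence of Pedigree
        Validated pedigrees; phenotypes are recoded internally for ``trait``.
    marker_map : MarkerMap
        Map the genotype columns refer to.
    trait : {"ASD", "ASD_BAP"}
        Analysis phenotype.  BAP members count as unaffected under ``ASD``
        and as affected under ``ASD_BAP``.
    config : PplConfig, optional
        Integration grids, prior π and accumulation mode; defaults to the
        coarse scan grid with sequential updating.
    """

    def __init__(
        self,
        pedigrees,
        marker_map: MarkerMap,
        trait: Trait | str = Trait.ASD,
        config: PplConfig | None = None,
    ):
        self.trait = Trait(trait)
        self.marker_map = marker_map
        self.config = config or PplConfig.coarse()
        self.pedigrees = [recode_phenotypes(p, self.trait) for p in pedigrees]

    @classmethod
    def from_linkage(
        cls,
        ped_path,
        map_path,
        trait: Trait | str = Trait.ASD,
        config: PplConfig | None = None,
        qc: QcConfig | None = None,
    ) -> "LinkageScanModel":
        """Build a model straight from LINKAGE PED/map files, optionally
        running the QC pipeline first (pass a QcConfig to enable it)."""
        pedigrees, marker_map = read_linkage(ped_path, map_path)
        if qc is not None:
            pedigrees, marker_map, _ = run_qc(pedigrees, marker_map, qc)
        return cls(pedigrees, marker_map, trait, config)

    def run_qc(self, qc: QcConfig | None = None) -> QcReport:
        """Clean the cohort in place (missingness → Mendel → HWE → LD)."""
        cleaned, cleaned_map, rep = run_qc(self.pedigrees, self.marker_map, qc)
        self.pedigrees = cleaned
        self.marker_map = cleaned_map
        return rep

    def fit(self, mode: Mode | str | None = None) -> "LinkageScanResults":
        """Run the scan and return the results object."""
        config = self.config
        if mode is not None and Mode(mode) != config.mode:
            config = PplConfig(
                prior_pi=config.prior_pi,
                alpha_grid=config.alpha_grid,
                p_grid=config.p_grid,
                penetrance_grid=list(config.penetrance_grid),
                theta_grid=config.theta_grid,
                theta_weights=config.theta_weights,
                mode=Mode(mode),
            )
        scan = genome_scan(self.pedigrees, self.marker_map, config)
        return LinkageScanResults(self, scan)


@dataclass
class LinkageScanResults:
    """Fitted PPL track with reporting conveniences."""

    model: LinkageScanModel
    scan: ScanResult

    @property
    def frame(self):
        return self.scan.frame

    @property
    def ppl(self):
        return self.scan.ppl

    def call_peaks(self, salience_min: float = report.NARROW, annotation=None):
        return report.call_peaks(self.scan, salience_min, annotation)

    def fraction_against(self, threshold: float | None = None) -> float:
        return fraction_against(self.scan, threshold)

    def update(self, other: "LinkageScanResults | ScanResult") -> "LinkageScanResults":
        """Sequentially update with an independently analysed cohort."""
        other_scan = other.scan if isinstance(other, LinkageScanResults) else other
        return LinkageScanResults(self.model, self.scan.update(other_scan))

    def plot(self, out_prefix: str, ylim=(0.0, 1.0), fmt: str = "png"):
        label = self.model.trait.value
        return report.plot_tracks({label: self.scan}, out_prefix, ylim, fmt)

    def summary(self) -> str:
        scan = self.scan
        counts = pedigree_summary(self.model.pedigrees)
        agg = counts.iloc[-1]
        peaks = self.call_peaks()
        lines = [
            "Posterior Probability of Linkage — scan summary",
            "=" * 56,
            f"trait:            {self.model.trait.value}",
            f"mode:             {scan.mode.value}",
            f"prior pi:         {scan.prior_pi:g}",
            f"pedigrees:        {len(self.model.pedigrees)} "
            f"({int(agg['members'])} members, {int(agg['asd'])} ASD, {int(agg['bap'])} BAP)",
            f"positions:        {len(scan.frame)} markers, "
            f"{scan.frame['chrom'].nunique()} chromosomes",
            f"grid points:      {scan.grid_size}",
            f"max PPL:          {scan.ppl.max():.4f} "
            f"at {scan.frame.loc[scan.frame['ppl'].idxmax(), 'marker']}",
            f"evidence against: {self.fraction_against():.1f}% of positions "
            f"(PPL <= {scan.prior_pi:g})",
            "-" * 56,
        ]
        if peaks:
            lines.append("salient peaks (PPL >= 0.20):")
            lines.append("chrom  peak_cM    PPL    narrow        intermed      broad")
            for p in peaks:
                lines.append(
                    f"{p.chromosome:>5}  {p.peak_cm:7.2f}  {p.peak_ppl:5.3f}  "
                    f"[{p.narrow[0]:.2f},{p.narrow[1]:.2f}]  "
                    f"[{p.intermediate[0]:.2f},{p.intermediate[1]:.2f}]  "
                    f"[{p.broad[0]:.2f},{p.broad[1]:.2f}]"
                )
        else:
            lines.append("no salient peaks (all PPL < 0.20)")
        return "\n".join(lines)
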