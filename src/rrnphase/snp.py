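"""Intragenomic SNP calling from substitution profiles.

True copy-variant SNPs sit at stoichiometric fractions (k/C for k of C
gene copies) far above the background sequencing-error fractions, so
they are separable by a robust outlier rule on the distribution of
per-position variant fractions: positions more than a multiple of the
interquartile range above the upper quartile are called.  Two QC gates
guard the call set: samples with too few aligned reads lack the
signal-to-noise for phasing, and samples with SNPs at an implausibly
large share of positions are treated as impure (mixed) isolates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import SubstitutionProfile

QC_PASS = "pass"
QC_FAIL_LOW_DEPTH = "fail_low_depth"
QC_FAIL_IMPURE = "fail_impure"


@dataclass(frozen=True)
class SnpThresholds:
    """Thresholds of the multi-step SNP filter.

    min_reads
        Samples with fewer aligned reads are discarded (default 200).
    iqr_multiplier
        A position is a SNP when its variant fraction exceeds
        Q3 + multiplier * IQR (default 9).
    max_snp_position_fraction
        Samples with SNPs at more than this share of aligned positions
        are discarded as impure (default 0.03).
    quartile_method
        Quantile interpolation passed to numpy (default ``"linear"``,
        the common type-7 convention).
    """

    min_reads: int = 200
    iqr_multiplier: float = 9.0
    max_snp_position_fraction: float = 0.03
    quartile_method: str = "linear"


@dataclass
class SNPCallSet:
    """Positions flagged as intragenomic SNPs plus the QC verdict.

    When QC fails the flagged positions are withheld (empty mapping);
    the candidate count is retained in ``n_candidates`` for reporting.
    ``snp_fractions`` maps 1-based reference position to the variant
    fraction observed there.
    """

    reference_id: str
    qc_status: str
    thresholds: SnpThresholds
    snp_fractions: dict[int, float] = field(default_factory=dict)
    n_reads: int = 0
    n_positions: int = 0  # aligned (covered) positions used for the IQR
    n_candidates: int = 0
    cutoff: float = float("nan")  # fraction threshold actually applied

    @property
    def positions(self) -> list[int]:
        return sorted(self.snp_fractions)

    def to_frame(self) -> pd.DataFrame:
        pos = self.positions
        return pd.DataFrame({
            "ref_id": self.reference_id,
            "pos": pos,
            "variant_fraction": [self.snp_fractions[p] for p in pos],
        })

    def qc_report(self) -> dict:
        return {
            "reference_id": self.reference_id,
            "qc_status": self.qc_status,
            "n_reads": self.n_reads,
            "n_aligned_positions": self.n_positions,
            "n_snp_candidates": self.n_candidates,
            "n_snps_reported": len(self.snp_fractions),
            "fraction_cutoff": None if np.isnan(self.cutoff) else self.cutoff,
            "thresholds": {
                "min_reads": self.thresholds.min_reads,
                "iqr_multiplier": self.thresholds.iqr_multiplier,
                "max_snp_position_fraction":
                    self.thresholds.max_snp_position_fraction,
                "positions_basis": "aligned-covered length",
            },
        }


def call_snps(profile: SubstitutionProfile,
              thresholds: SnpThresholds = SnpThresholds()) -> SNPCallSet:
    """Apply the multi-step IQR filter to a substitution profile.

    Steps: (1) discard samples with fewer than ``min_reads`` aligned
    reads; (2) compute Q1/Q3/IQR of the variant fractions over all
    aligned (covered) positions and flag positions above
    Q3 + ``iqr_multiplier`` * IQR; (3) discard samples whose flagged
    positions exceed ``max_snp_position_fraction`` of aligned positions.

    A degenerate profile (IQR == 0, e.g. error-free reads) falls back
    to a cutoff of Q3 plus one read's worth of frequency (1 / n_reads)
    so that a perfect profile does not have every position flagged.
    """
    if profile.n_reads < thresholds.min_reads:
        return SNPCallSet(reference_id=profile.reference_id,
                          qc_status=QC_FAIL_LOW_DEPTH, thresholds=thresholds,
                          n_reads=profile.n_reads)

    covered = np.flatnonzero(profile.depth > 0)
    fractions = profile.variant_fraction[covered]
    n_pos = covered.size
    if n_pos == 0:
        return SNPCallSet(reference_id=profile.reference_id,
                          qc_status=QC_FAIL_LOW_DEPTH, thresholds=thresholds,
                          n_reads=profile.n_reads)

    q1, q3 = np.percentile(fractions, [25, 75],
                           method=thresholds.quartile_method)
    iqr = q3 - q1
    if iqr > 0:
        cutoff = q3 + thresholds.iqr_multiplier * iqr
    else:
        cutoff = q3 + 1.0 / profile.n_reads
    flagged = covered[fractions > cutoff]

    if flagged.size > thresholds.max_snp_position_fraction * n_pos:
        return SNPCallSet(reference_id=profile.reference_id,
                          qc_status=QC_FAIL_IMPURE, thresholds=thresholds,
                          n_reads=profile.n_reads, n_positions=n_pos,
                          n_candidates=int(flagged.size), cutoff=cutoff)

    snps = {int(p) + 1: float(profile.variant_fraction[p]) for p in flagged}
    return SNPCallSet(reference_id=profile.reference_id, qc_status=QC_PASS,
                      thresholds=thresholds, snp_fractions=snps,
                      n_reads=profile.n_reads, n_positions=n_pos,
                      n_candidates=int(flagged.size), cutoff=cutoff)
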