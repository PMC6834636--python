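"""Seeded end-to-end experiments on synthetic data.

Each function simulates a study condition (one strain with seven
polymorphic gene copies, a two-strain mixture, replicate runs of one
isolate, a species database with localized discriminating sites, ...),
runs the pipeline on the simulated reads, and reports summary numbers.
They are used both by the acceptance checks and as worked examples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import ISOLATE_SCORING, ScoringScheme
from .compare import (GeneCopySet, estimate_measurement_error,
                      predicted_profile, profiles_differ)
from .pipeline import DEFAULT_BAND, phase_sample
from .profiles import deletion_rate_by_runlength, homopolymer_runs
from .regions import PrimerPair
from .resolution import region_resolution_summary
from .simulate import (ErrorModel, SyntheticTruth, make_community,
                       make_gene_copy_set, make_species_database, random_gene,
                       simulate_ccs_reads)
from .snp import QC_PASS, SnpThresholds

#: study conditions: seven gene copies, 500 CCS reads per sample, 0.5%
#: substitution error with rarer indels
N_COPIES = 7
N_READS = 500
CCS_MODEL = ErrorModel(substitution_rate=0.005, insertion_rate=0.001,
                       deletion_rate_base=0.002, homopolymer_factor=2.0)

#: the stoichiometry-recovery and mixture-linearity conditions are defined
#: with substitution error alone (0.5%); indel behaviour has its own
#: experiment.  With homopolymer-prone deletions switched on, a planted
#: variant that extends a run loses part of its substitution signal to
#: deletion conversion at the run boundary (see the methods note).
SUBSTITUTION_ONLY = ErrorModel(substitution_rate=0.005, insertion_rate=0.0,
                               deletion_rate_base=0.0,
                               homopolymer_factor=1.0)

_SCORING = ISOLATE_SCORING


def _spawn(seed: int, n: int) -> list[int]:
    """Derive n child seeds below 2**31 from one master seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2 ** 31 - 1, size=n)]


@dataclass
class RecoveryRun:
    all_loci_recovered: bool
    n_false_positives: int
    max_abs_fraction_error: float
    qc_status: str
    # called variant fraction per planted stoichiometry k (NaN if missed)
    fraction_by_k: dict[int, float] = None


def snp_recovery_run(seed: int, n_reads: int = N_READS,
                     C: int = N_COPIES,
                     model: ErrorModel = SUBSTITUTION_ONLY) -> RecoveryRun:
    """One strain, loci planted at every stoichiometry 1/C .. (C-1)/C.

    Simulates reads, phases them against the designated reference copy,
    and compares the called SNPs with the generator's truth table.
    """
    rng = np.random.default_rng(seed)
    base = random_gene(1500, rng)
    gcs, truth = make_gene_copy_set(base, C, n_snp_loci=C - 1,
                                    copies_per_locus=list(range(1, C)),
                                    seed=rng)
    reads = simulate_ccs_reads(truth, n_reads, model, seed=rng)
    phased = phase_sample(reads, reference=gcs.reference_copy,
                          reference_id=gcs.genome_id, scoring=_SCORING,
                          band=DEFAULT_BAND)
    planted = {pos: len(carriers)
               for pos, carriers in truth.planted_variants[gcs.genome_id]}
    called = phased.calls.snp_fractions
    missing = set(planted) - set(called)
    false = set(called) - set(planted)
    max_err = max((abs(called[p] - planted[p] / C) for p in planted
                   if p in called), default=float("inf"))
    if missing:
        max_err = float("inf")
    by_k = {k: float(called[p]) if p in called else float("nan")
            for p, k in planted.items()}
    return RecoveryRun(all_loci_recovered=not missing,
                       n_false_positives=len(false),
                       max_abs_fraction_error=max_err,
                       qc_status=phased.calls.qc_status,
                       fraction_by_k=by_k)


def snp_recovery_experiment(seed: int, n_runs: int = 100,
                            n_reads: int = N_READS,
                            C: int = N_COPIES) -> dict:
    """Repeat the recovery run under independent seeds and summarise.

    Besides per-run recovery and false-positive counts, reports the
    mean called fraction per planted stoichiometry k across runs and
    its worst absolute deviation from k/C — the estimator's bias, which
    is what a fixed absolute tolerance can bound (a single run's locus
    estimate carries binomial noise of ~0.02 at 500 reads).
    """
    runs = [snp_recovery_run(s, n_reads=n_reads, C=C)
            for s in _spawn(seed, n_runs)]
    clean = [r for r in runs
             if r.all_loci_recovered and r.n_false_positives == 0]
    finite = [r.max_abs_fraction_error for r in runs
              if np.isfinite(r.max_abs_fraction_error)]
    mean_by_k = {k: float(np.nanmean([r.fraction_by_k[k] for r in runs]))
                 for k in range(1, C)}
    bias = max(abs(mean_by_k[k] - k / C) for k in mean_by_k)
    return {
        "n_runs": n_runs,
        "runs_all_loci_recovered": sum(r.all_loci_recovered for r in runs),
        "runs_without_false_positives":
            sum(r.n_false_positives == 0 for r in runs),
        "runs_fully_clean": len(clean),
        "max_abs_fraction_error_single_run":
            max(finite) if finite else float("inf"),
        "mean_fraction_by_k": mean_by_k,
        "max_abs_bias_of_mean_fraction": float(bias),
    }


def mixture_experiment(seed: int, w1: float = 0.7, n_reads: int = 1000,
                       C: int = N_COPIES,
                       model: ErrorModel = SUBSTITUTION_ONLY) -> dict:
    """Two strains of one species mixed w1 : 1-w1.

    Both strains derive from one base gene (so they share the reference
    copy) but carry copy variants at distinct loci.  The observed
    substitution profile of the pooled reads is compared with the
    abundance-weighted combination w1*f1 + w2*f2 at every planted
    locus; deviations are reported in binomial-SD units.
    """
    rng = np.random.default_rng(seed)
    base = random_gene(1500, rng)
    a, truth_a = make_gene_copy_set(base, C, 3, [1, 3, 5], seed=rng,
                                    genome_id="strainA")
    b, truth_b = make_gene_copy_set(base, C, 3, [2, 4, 6], seed=rng,
                                    genome_id="strainB")
    planted = {"strainA": truth_a.planted_variants["strainA"],
               "strainB": truth_b.planted_variants["strainB"]}
    reads, truth = make_community([a, b], [w1, 1.0 - w1], n_reads, model,
                                  seed=rng, planted_variants=planted)
    phased = phase_sample(reads, reference=base, reference_id="base",
                          scoring=_SCORING, band=DEFAULT_BAND)

    expected: dict[int, float] = {}
    for genome_id, w in (("strainA", w1), ("strainB", 1.0 - w1)):
        for pos, carriers in planted[genome_id]:
            expected[pos] = expected.get(pos, 0.0) + w * len(carriers) / C
    devs = []
    for pos, f_exp in sorted(expected.items()):
        depth = int(phased.profile.depth[pos - 1])
        f_obs = phased.profile.fraction_at(pos)
        sd = np.sqrt(f_exp * (1 - f_exp) / depth)
        devs.append(abs(f_obs - f_exp) / sd)
    return {
        "n_loci": len(expected),
        "max_dev_sd_units": float(max(devs)),
        "loci_within_3sd": int(sum(d <= 3.0 for d in devs)),
        "n_reads": n_reads,
    }


def homopolymer_experiment(seed: int, n_reads: int = 400,
                           max_run: int = 6,
                           model: ErrorModel = CCS_MODEL) -> dict:
    """Deletion-rate recovery across homopolymer run lengths.

    The reference carries engineered runs of every length up to
    ``max_run``; reads simulated with a homopolymer factor > 1 must
    show a per-run-length mean deletion fraction that increases
    strictly with run length.
    """
    rng = np.random.default_rng(seed)
    # build a gene with planted runs of each length, separated by
    # alternating dimers that cannot extend a run
    pieces = []
    bases = "ACGT"
    k = 0
    for rep in range(12):
        for run in range(1, max_run + 1):
            b = bases[k % 4]
            sep = "AC" if b in "GT" else "GT"
            pieces.append(sep + b * run)
            k += 1
    gene = ("".join(pieces) + random_gene(200, rng))[:1500]
    if len(gene) < 1300:
        gene = gene + random_gene(1500 - len(gene), rng)
    gcs = GeneCopySet(genome_id="g", copies=[gene])
    truth = SyntheticTruth(genomes=[gcs], planted_variants={},
                           abundances={"g": 1.0})
    reads = simulate_ccs_reads(truth, n_reads, model, seed=rng)
    phased = phase_sample(reads, reference=gene, reference_id="g",
                          scoring=ScoringScheme(min_score=0), band=DEFAULT_BAND,
                          min_len=len(gene) - 100, max_len=len(gene) + 100)
    table = deletion_rate_by_runlength(phased.tallies)
    table = table[table["run_length"] <= max_run]
    rates = table.sort_values("run_length")["mean_deletion_fraction"].to_numpy()
    return {
        "run_lengths": table.sort_values("run_length")["run_length"].tolist(),
        "mean_deletion_fraction": rates.tolist(),
        "strictly_increasing": bool(np.all(np.diff(rates) > 0)),
    }


# primer pairs for the synthetic benchmark database: FULL spans the whole
# gene, SUB a window that can be placed away from the discriminating sites
_FULL_F = "AGAGTTTGATCCTGGCTCAG"  # 27F-like, planted conserved
_FULL_R_RC = "AAGTCGTAACAAGGTAACCG"  # site on template; primer is its RC
_SUB_F = "GTGCCAGCAGCCGCGGTAAT"  # 515F-like
_SUB_R_RC = "ATTAGATACCCTGGTAGTCC"  # site on template


def synthetic_benchmark_db(seed: int, n_species: int = 40,
                           variable_window: tuple[int, int] = (900, 1150),
                           n_variable_sites: int = 20):
    """Species database whose discriminating sites sit in one window.

    The FULL region (between the terminal primer sites) contains the
    window; the SUB region (between the internal primer sites at
    421-690) does not, so SUB amplicons are identical across species.
    """
    conserved = [(1, _FULL_F), (421, _SUB_F), (691, _SUB_R_RC),
                 (1481, _FULL_R_RC)]
    db = make_species_database(n_species, length=1500,
                               variable_windows=[variable_window],
                               n_variable_sites=n_variable_sites,
                               conserved=conserved, seed=seed)
    primers = [
        PrimerPair("FULL", _FULL_F,
                   _revcomp(_FULL_R_RC), max_mismatches=3),
        PrimerPair("SUB", _SUB_F,
                   _revcomp(_SUB_R_RC), max_mismatches=3),
    ]
    return db, primers


def _revcomp(seq: str) -> str:
    from .alignment import reverse_complement
    return reverse_complement(seq)


def region_resolution_experiment(seed: int, cutoff: float = 80.0) -> dict:
    """Resolution ordering on the synthetic benchmark database."""
    db, primers = synthetic_benchmark_db(seed)
    summary = region_resolution_summary(db, primers, cutoff=cutoff, seed=seed)
    by_region = summary.set_index("region")
    full = by_region.loc["FULL"]
    sub = by_region.loc["SUB"]
    return {
        "full_unclassifiable": float(full["fraction_unclassifiable"]),
        "sub_unclassifiable": float(sub["fraction_unclassifiable"]),
        "full_self_recovery":
            1.0 - float(full["fraction_misclassified"]),
        "n_species": int(full["n_sources"]),
    }


def replicate_error_experiment(seed: int, n_isolates: int = 6,
                               n_replicates: int = 2,
                               n_reads: int = 400,
                               model: ErrorModel = CCS_MODEL) -> dict:
    """Cohort zeta_w from replicate sequencing of synthetic isolates."""
    seeds = _spawn(seed, n_isolates)
    replicates = {}
    for i, s in enumerate(seeds):
        rng = np.random.default_rng(s)
        base = random_gene(1500, rng)
        gcs, truth = make_gene_copy_set(base, N_COPIES, 4, [1, 2, 3, 5],
                                        seed=rng, genome_id=f"iso{i}")
        profs, calls = [], []
        for _ in range(n_replicates):
            reads = simulate_ccs_reads(truth, n_reads, model, seed=rng)
            truth.reads.clear()
            phased = phase_sample(reads, reference=gcs.reference_copy,
                                  scoring=_SCORING, band=DEFAULT_BAND)
            profs.append(phased.profile)
            calls.append(phased.calls)
        replicates[f"iso{i}"] = (profs, calls)
    est = estimate_measurement_error(replicates)
    return {
        "n_isolates": n_isolates,
        "median_zeta_w_pct": est.median,
        "mean_zeta_w_pct": est.mean,
        "sd_zeta_w_pct": est.sd,
        "difference_threshold_pct": est.difference_threshold,
    }


def strain_discrimination_experiment(seed: int, n_pairs: int = 10,
                                     n_self_pairs: int = 5,
                                     n_reads: int = N_READS,
                                     self_check_reads: int = 2000,
                                     threshold_pct: float = 6.58,
                                     model: ErrorModel = CCS_MODEL) -> dict:
    """Separation of distinct strains vs. stability of identical ones.

    For each trial, two strains of one species differ at two loci by
    at least 2/C in copy-variant stoichiometry; both are phased at
    ``n_reads`` depth and compared with the replicate-error threshold.
    A re-run of strain A must not be declared different from itself;
    the self-comparison uses ``self_check_reads`` because a fraction
    estimated from n reads carries binomial noise ~sqrt(f(1-f)/n), and
    only at a few thousand reads does a 6.58-point threshold sit >4 SD
    above the run-to-run difference at every k/7 stoichiometry.
    """
    C = N_COPIES
    separated = 0
    self_split = 0
    for pair_idx, s in enumerate(_spawn(seed, n_pairs)):
        rng = np.random.default_rng(s)
        base = random_gene(1500, rng)
        a, ta = make_gene_copy_set(base, C, 2, [2, 3], seed=rng,
                                   genome_id="A")
        # strain B: same loci, shifted stoichiometry (>= 2/C apart)
        b_copies = [list(base) for _ in range(C)]
        for (pos, carriers), k_b in zip(ta.planted_variants["A"], (4, 5)):
            alt = a.copies[carriers[0]][pos - 1]
            for c in range(1, k_b + 1):
                b_copies[c][pos - 1] = alt
        b = GeneCopySet(genome_id="B", copies=["".join(c) for c in b_copies])

        def _phase(gcs, n, sd):
            truth = SyntheticTruth(genomes=[gcs], planted_variants={},
                                   abundances={gcs.genome_id: 1.0})
            reads = simulate_ccs_reads(truth, n, model, seed=sd)
            return phase_sample(reads, reference=base, scoring=_SCORING,
                                band=DEFAULT_BAND).calls

        calls_a = _phase(a, n_reads, int(rng.integers(2 ** 31)))
        calls_b = _phase(b, n_reads, int(rng.integers(2 ** 31)))
        if profiles_differ(calls_a, calls_b, threshold_pct):
            separated += 1
        if pair_idx < n_self_pairs:
            deep_a1 = _phase(a, self_check_reads,
                             int(rng.integers(2 ** 31)))
            deep_a2 = _phase(a, self_check_reads,
                             int(rng.integers(2 ** 31)))
            if profiles_differ(deep_a1, deep_a2, threshold_pct):
                self_split += 1
    return {"n_pairs": n_pairs, "pairs_separated": separated,
            "n_self_pairs": n_self_pairs,
            "identical_pairs_split": self_split}
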