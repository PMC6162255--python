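"""Synthetic two-group LC-MS cohort generator with known ground truth.

Emulates the study design this pipeline targets: 9 T2DM vs 9 control
subjects, triplicate LC-MS runs per subject (54 runs), per-run unique
mass class (UMC) feature tables with ppm-scale mass error, run-specific
affine elution drift, log-normal intensities, sparse (~10%) MS/MS
identification and intensity-dependent dropout, plus a planted fraction
of proteins with >= 1.5-fold abundance differences between groups.

Every downstream stage (NET calibration, AMT matching, alignment,
differential testing) can therefore be scored against a hidden manifest
of true peptide identities and planted fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GroundTruth",
    "CohortDesign",
    "NoiseModel",
    "generate_ground_truth",
    "simulate_run",
    "simulate_cohort",
    "generate_annotations",
    "generate_interactions",
]

GROUP_CASE = "T2DM"
GROUP_CONTROL = "control"


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


class DesignError(ValueError):
    """Subject/run inconsistent with the cohort design."""


@dataclass(frozen=True)
class GroundTruth:
    """Planted proteome: peptides, masses, elution order and DE effects.

    peptide_map maps peptide id -> (protein id, theoretical monoisotopic
    mass in Da, true NET in [0, 1]). de_proteins maps protein id to its
    signed log2 fold change (T2DM relative to control); proteins absent
    from the mapping are null. base_log2_abundance is the control-group
    mean log2 intensity of each peptide.
    """

    proteins: tuple[str, ...]
    peptide_map: dict[str, tuple[str, float, float]]
    de_proteins: dict[str, float]
    base_log2_abundance: dict[str, float]

    def __post_init__(self) -> None:
        for pid, lfc in self.de_proteins.items():
            if abs(lfc) < np.log2(1.5) - 1e-12:
                raise ConfigurationError(
                    f"planted |log2fc| for {pid} below log2(1.5): {lfc}"
                )
        for pep, (prot, mass, net) in self.peptide_map.items():
            if not (0.0 <= net <= 1.0):
                raise ConfigurationError(f"true NET of {pep} outside [0,1]: {net}")
            if mass <= 0:
                raise ConfigurationError(f"nonpositive mass for {pep}")
            if prot not in self.proteins:
                raise ConfigurationError(f"{pep} maps to unknown protein {prot}")

    @property
    def peptides(self) -> list[str]:
        return list(self.peptide_map)

    def protein_of(self, peptide_id: str) -> str:
        return self.peptide_map[peptide_id][0]

    def peptide_log2fc(self, peptide_id: str) -> float:
        return self.de_proteins.get(self.protein_of(peptide_id), 0.0)

    def protein_map(self) -> pd.Series:
        """peptide id -> protein id as a pandas Series."""
        return pd.Series(
            {p: v[0] for p, v in self.peptide_map.items()}, name="protein_id"
        )


@dataclass(frozen=True)
class CohortDesign:
    """Two-group balanced design with technical replicates per subject."""

    n_per_group: int = 9
    n_replicates: int = 3
    group_labels: tuple[str, str] = (GROUP_CASE, GROUP_CONTROL)

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")

    @property
    def n_runs(self) -> int:
        return 2 * self.n_per_group * self.n_replicates

    def subjects(self) -> list[tuple[str, str]]:
        """(subject_id, group) pairs, cases first."""
        out = []
        for gi, group in enumerate(self.group_labels):
            for s in range(self.n_per_group):
                out.append((f"{group}_{s + 1:02d}", group))
        return out

    def sample_sheet(self) -> pd.DataFrame:
        rows = []
        for subject, group in self.subjects():
            for rep in range(1, self.n_replicates + 1):
                rows.append(
                    {
                        "run_id": f"{subject}_r{rep}",
                        "subject_id": subject,
                        "group": group,
                        "replicate": rep,
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise settings for one simulated cohort.

    mass_error_ppm_sd      sd of the per-feature mass error, ppm
    net_drift_slope_sd     sd of the run-specific multiplicative elution
                           drift (slope drawn as scan_range*(1+N(0,sd)))
    net_drift_intercept_sd sd of the run-specific elution offset, in NET
                           units before scan scaling
    net_noise_sd           per-feature elution jitter, NET units
    log2_intensity_sd      per-run technical intensity noise, log2 units
    log2_subject_sd        between-subject biological variation, log2
    id_rate                probability a feature carries its MS/MS id
    dropout_midpoint       log2 intensity with 50% detection chance;
                           None disables dropout
    dropout_steepness      logistic slope of the detection curve
    """

    mass_error_ppm_sd: float = 3.0
    net_drift_slope_sd: float = 0.03
    net_drift_intercept_sd: float = 0.02
    net_noise_sd: float = 0.005
    log2_intensity_sd: float = 0.25
    log2_subject_sd: float = 0.35
    id_rate: float = 0.104
    dropout_midpoint: float | None = 18.5
    dropout_steepness: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.id_rate <= 1.0):
            raise ConfigurationError("id_rate must lie in (0, 1]")
        for name in (
            "mass_error_ppm_sd",
            "net_drift_slope_sd",
            "net_drift_intercept_sd",
            "net_noise_sd",
            "log2_intensity_sd",
            "log2_subject_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    def noiseless(self) -> "NoiseModel":
        """Copy with all stochastic perturbations switched off."""
        return replace(
            self,
            mass_error_ppm_sd=0.0,
            net_drift_slope_sd=0.0,
            net_drift_intercept_sd=0.0,
            net_noise_sd=0.0,
            log2_intensity_sd=0.0,
            log2_subject_sd=0.0,
            dropout_midpoint=None,
        )


def generate_ground_truth(
    n_proteins: int,
    peptides_per_protein: tuple[int, int] = (3, 8),
    de_fraction: float = 0.2,
    fold_change_range: tuple[float, float] = (1.5, 4.0),
    seed: int = 0,
) -> GroundTruth:
    """Draw a random proteome with a planted differentially expressed subset.

    Exactly ``round(de_fraction * n_proteins)`` proteins receive a signed
    log2 fold change with linear magnitude drawn uniformly from
    ``fold_change_range``; all sibling peptides of a DE protein share it.
    """
    if n_proteins < 1:
        raise ConfigurationError("n_proteins must be >= 1")
    if not (0.0 <= de_fraction <= 1.0):
        raise ConfigurationError("de_fraction must lie in [0, 1]")
    lo, hi = peptides_per_protein
    if not (1 <= lo <= hi):
        raise ConfigurationError("invalid peptides_per_protein range")
    flo, fhi = fold_change_range
    if flo < 1.5 or fhi < flo:
        raise ConfigurationError(
            "fold_change_range must satisfy 1.5 <= low <= high"
        )

    rng = np.random.default_rng(seed)
    proteins = tuple(f"P{i + 1:05d}" for i in range(n_proteins))

    n_de = int(round(de_fraction * n_proteins))
    de_idx = rng.choice(n_proteins, size=n_de, replace=False)
    de_proteins: dict[str, float] = {}
    for i in de_idx:
        fold = rng.uniform(flo, fhi)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        de_proteins[proteins[i]] = sign * float(np.log2(fold))

    peptide_map: dict[str, tuple[str, float, float]] = {}
    base: dict[str, float] = {}
    for i, prot in enumerate(proteins):
        k = int(rng.integers(lo, hi + 1))
        for j in range(k):
            pep = f"{prot}.pep{j + 1:02d}"
            mass = float(rng.uniform(700.0, 4000.0))
            net = float(rng.uniform(0.02, 0.98))
            peptide_map[pep] = (prot, mass, net)
            base[pep] = float(rng.normal(22.0, 2.0))

    return GroundTruth(
        proteins=proteins,
        peptide_map=peptide_map,
        de_proteins=de_proteins,
        base_log2_abundance=base,
    )


def _subject_rng(noise: NoiseModel, subject: str) -> np.random.Generator:
    # subject effects must be shared across that subject's replicates
    key = np.frombuffer(subject.encode(), dtype=np.uint8)
    return np.random.default_rng([noise.seed, 1, *key.tolist()])


def _run_rng(noise: NoiseModel, subject: str, replicate: int) -> np.random.Generator:
    key = np.frombuffer(subject.encode(), dtype=np.uint8)
    return np.random.default_rng([noise.seed, 2, replicate, *key.tolist()])


# scan-scale constants for the affine elution drift: elution is emitted in
# arbitrary scan units so NET computation/calibration downstream is exercised
_SCAN_RANGE = 3000.0
_SCAN_OFFSET = 500.0


def simulate_run(
    truth: GroundTruth,
    subject: str,
    group: str,
    replicate: int,
    noise: NoiseModel,
    design: CohortDesign | None = None,
) -> pd.DataFrame:
    """Simulate one LC-MS run as a UMC feature table.

    Columns: run_id, umc_id, monoisotopic_mass_da, elution_scan,
    intensity, charge, peptide_id (empty string if unidentified) and the
    hidden column true_peptide_id used only for manifest bookkeeping.
    """
    if design is not None:
        valid = {s for s, _ in design.subjects()}
        if subject not in valid:
            raise DesignError(f"unknown subject {subject!r}")
        if group not in design.group_labels:
            raise DesignError(f"unknown group {group!r}")

    run_id = f"{subject}_r{replicate}"
    peptides = truth.peptides
    n = len(peptides)
    srng = _subject_rng(noise, subject)
    rng = _run_rng(noise, subject, replicate)

    th_mass = np.array([truth.peptide_map[p][1] for p in peptides])
    th_net = np.array([truth.peptide_map[p][2] for p in peptides])
    base = np.array([truth.base_log2_abundance[p] for p in peptides])
    lfc = np.array([truth.peptide_log2fc(p) for p in peptides])
    effect = lfc if group == GROUP_CASE else np.zeros(n)

    # subject-level biological variation, identical across replicates
    subj_eff = srng.normal(0.0, noise.log2_subject_sd, size=n)

    # per-run affine elution drift in scan units; b=1,a=0 when drift sds are 0
    if noise.net_drift_slope_sd == 0 and noise.net_drift_intercept_sd == 0:
        a, b = 0.0, 1.0
    else:
        b = _SCAN_RANGE * (1.0 + rng.normal(0.0, noise.net_drift_slope_sd))
        a = _SCAN_OFFSET + _SCAN_RANGE * rng.normal(0.0, noise.net_drift_intercept_sd)

    ppm_err = rng.normal(0.0, noise.mass_error_ppm_sd, size=n)
    mass = th_mass * (1.0 + ppm_err / 1e6)
    elut = a + b * (th_net + rng.normal(0.0, noise.net_noise_sd, size=n))
    log2_int = base + effect + subj_eff + rng.normal(
        0.0, noise.log2_intensity_sd, size=n
    )
    intensity = np.exp2(log2_int)

    if noise.dropout_midpoint is None:
        keep = np.ones(n, dtype=bool)
    else:
        p_detect = 1.0 / (
            1.0
            + np.exp(-noise.dropout_steepness * (log2_int - noise.dropout_midpoint))
        )
        keep = rng.random(n) < p_detect

    identified = rng.random(n) < noise.id_rate
    charge = rng.integers(2, 4, size=n)

    df = pd.DataFrame(
        {
            "run_id": run_id,
            "umc_id": [f"{run_id}_u{i + 1:05d}" for i in range(n)],
            "monoisotopic_mass_da": mass,
            "elution_scan": elut,
            "intensity": intensity,
            "charge": charge,
            "peptide_id": np.where(identified, peptides, ""),
            "true_peptide_id": peptides,
        }
    )
    return df.loc[keep].reset_index(drop=True)


def simulate_cohort(
    truth: GroundTruth,
    design: CohortDesign | None = None,
    noise: NoiseModel | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Simulate every run of a cohort.

    Returns (runs, sample_sheet, manifest): ``runs`` maps run id to its
    public feature table (hidden truth column removed); ``manifest`` holds
    one row per emitted feature with its true peptide and protein identity
    plus the planted protein log2 fold change, for scoring downstream
    assignments and DEP calls against ground truth.
    """
    design = design or CohortDesign()
    noise = noise or NoiseModel()
    sheet = design.sample_sheet()

    runs: dict[str, pd.DataFrame] = {}
    manifest_parts = []
    for row in sheet.itertuples(index=False):
        df = simulate_run(
            truth, row.subject_id, row.group, row.replicate, noise, design=design
        )
        manifest_parts.append(df[["run_id", "umc_id", "true_peptide_id"]])
        runs[row.run_id] = df.drop(columns="true_peptide_id")

    manifest = pd.concat(manifest_parts, ignore_index=True)
    manifest["protein_id"] = manifest["true_peptide_id"].map(
        lambda p: truth.protein_of(p)
    )
    manifest["planted_log2fc"] = manifest["protein_id"].map(
        lambda pr: truth.de_proteins.get(pr, 0.0)
    )
    return runs, sheet, manifest


def generate_annotations(
    truth: GroundTruth, n_terms: int = 20, extra_membership: float = 0.1, seed: int = 0
):
    """Random functional annotation terms over the planted proteome.

    Proteins are partitioned into ``n_terms`` blocks (each a term), then
    each protein additionally joins every other term with probability
    ``extra_membership``, giving overlapping gene sets like real GO
    slims. Returns a list of AnnotationSet.
    """
    from .enrichment import AnnotationSet

    rng = np.random.default_rng(seed)
    prots = list(truth.proteins)
    rng.shuffle(prots)
    blocks = np.array_split(np.array(prots, dtype=object), n_terms)
    terms = []
    for i, block in enumerate(blocks):
        members = set(block.tolist())
        others = [p for p in truth.proteins if p not in members]
        extra = rng.random(len(others)) < extra_membership
        members |= {p for p, e in zip(others, extra) if e}
        if members:
            terms.append(
                AnnotationSet(f"GOBP:{i + 1:04d}", f"synthetic process {i + 1}",
                              frozenset(members))
            )
    return terms


def generate_interactions(
    truth: GroundTruth, mean_degree: float = 4.0, seed: int = 0
) -> pd.DataFrame:
    """Random PPI edge list over the planted proteome (id_a, id_b, source_db)."""
    rng = np.random.default_rng(seed)
    prots = np.array(truth.proteins, dtype=object)
    n = len(prots)
    n_edges = int(mean_degree * n / 2)
    a = rng.integers(0, n, size=2 * n_edges)
    b = rng.integers(0, n, size=2 * n_edges)
    ok = a != b
    pairs = {tuple(sorted((int(i), int(j)))) for i, j in zip(a[ok], b[ok])}
    pairs = sorted(pairs)[:n_edges]
    dbs = np.array(["BioGRID", "HPRD", "MINT", "BIND"], dtype=object)
    return pd.DataFrame(
        {
            "id_a": [prots[i] for i, _ in pairs],
            "id_b": [prots[j] for _, j in pairs],
            "source_db": dbs[rng.integers(0, 4, size=len(pairs))],
        }
    )
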