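"""Synthetic multicohort transcriptome and digital-pathology data.

Every downstream stage of the pipeline (scaler selection, classifier
extraction and reduction, cross-cohort validation, marker-panel search,
survival stratification) is exercised on data generated here with a
known ground truth, so parameter recovery can be tested without any
patient-level downloads.

The default transcriptome conditions mirror the study design: four
cohorts of 16 (8 NR / 8 R), 23, 38 and 299 samples with cohort-specific
location, scale and marginal-shape differences, and a small planted set
of response-informative genes.  The default pathology conditions are a
74-marker, two-compartment table for 55 + 36 patients with three
replicate tissue-microarray cores per patient and survival coupled to
the latent response through a proportional-hazards model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .classifiers import ExpressionCohort, GeneClassifier

__all__ = [
    "CohortSimSpec", "PathologySimSpec", "GroundTruth", "PathologyTable",
    "generate_cohorts", "generate_pathology", "simulate_survival",
    "synthetic_classifier_sets", "write_fixture",
    "read_expression_tsv", "write_expression_tsv",
    "read_gmt", "write_gmt", "read_pathology", "GENE_ALIASES",
]

#: A few synthetic gene IDs aliased to symbols that appear in worked
#: examples.  The aliases are labels only; no real biology is claimed.
GENE_ALIASES = {
    "G0000": "GLS", "G0001": "KEAP1", "G0002": "FOXA1", "G0003": "IL15RA",
    "G0004": "AFAP1", "G0005": "POU2F2", "G0006": "RFX7", "G0007": "DNMT3L",
}


# ---------------------------------------------------------------------------
# specifications and ground truth
# ---------------------------------------------------------------------------

@dataclass
class CohortSimSpec:
    """Conditions for the multicohort transcriptome simulator."""

    cohort_sizes: tuple[int, ...] = (16, 23, 38, 299)
    class_balance: float = 0.5
    n_genes: int = 1000
    n_informative: int = 20
    effect_size: float = 1.0
    cohort_shift: tuple[float, ...] | float = (0.0, 2.0, -1.0, 4.0)
    cohort_scale: tuple[float, ...] | float = (1.0, 1.5, 0.7, 2.0)
    shape: str = "lognormal"
    label_noise: float = 0.0
    cohort_ids: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if any(n < 4 for n in self.cohort_sizes):
            raise ValueError("cohort_sizes: every cohort must have >= 4 samples")
        if not (0.0 < self.class_balance < 1.0):
            raise ValueError("class_balance must lie strictly between 0 and 1")
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative cannot exceed n_genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.shape not in ("gaussian", "lognormal"):
            raise ValueError("shape must be 'gaussian' or 'lognormal'")
        scales = self._per_cohort(self.cohort_scale)
        if any(s <= 0 for s in scales):
            raise ValueError("cohort_scale entries must be > 0")
        if not (0.0 <= self.label_noise < 1.0):
            raise ValueError("label_noise must lie in [0, 1)")

    def _per_cohort(self, value) -> list[float]:
        k = len(self.cohort_sizes)
        if np.isscalar(value):
            return [float(value)] * k
        value = list(value)
        if len(value) != k:
            raise ValueError("per-cohort parameter length must match cohort_sizes")
        return [float(v) for v in value]

    def ids(self) -> list[str]:
        if self.cohort_ids is not None:
            if len(self.cohort_ids) != len(self.cohort_sizes):
                raise ValueError("cohort_ids length must match cohort_sizes")
            return list(self.cohort_ids)
        return [f"cohort{i + 1}" for i in range(len(self.cohort_sizes))]


@dataclass
class PathologySimSpec:
    """Conditions for the digital-pathology table simulator."""

    n_patients: tuple[int, int] = (55, 36)
    n_markers: int = 74
    n_predictive: int = 6
    effect_size: float = 2.0
    cores_per_patient: int = 3
    hazard_ratio: float = 2.5
    baseline_hazard: float = 0.02       # events per month for responders
    censor_rate: float = 0.2
    class_balance: tuple[float, float] = (34 / 55, 11 / 36)
    core_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.cores_per_patient < 1:
            raise ValueError("cores_per_patient must be >= 1")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.n_predictive > self.n_markers:
            raise ValueError("n_predictive cannot exceed n_markers")


@dataclass
class GroundTruth:
    """What the simulator planted, for parameter-recovery tests."""

    informative_genes: list[str] = field(default_factory=list)
    predictive_markers: dict[str, list[str]] = field(default_factory=dict)
    latent_response: dict[str, list[int]] = field(default_factory=dict)
    hazard_params: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "informative_genes": self.informative_genes,
            "predictive_markers": self.predictive_markers,
            "latent_response": self.latent_response,
            "hazard_params": self.hazard_params,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            informative_genes=list(d.get("informative_genes", [])),
            predictive_markers={k: list(v) for k, v in d.get("predictive_markers", {}).items()},
            latent_response={k: list(v) for k, v in d.get("latent_response", {}).items()},
            hazard_params=dict(d.get("hazard_params", {})),
        )


@dataclass
class PathologyTable:
    """Patients x markers x compartment intensities with survival annotations.

    ``means`` holds one column per ``<marker>__<compartment>`` (the mean
    over replicate cores); ``cores`` holds the per-core values in long
    form; ``clinical`` carries cohort tag (NAC/PCT), response label and
    the OS/PFS time and event columns.
    """

    clinical: pd.DataFrame
    means: pd.DataFrame
    cores: pd.DataFrame
    data_type: str = "raw"

    def __post_init__(self):
        if self.data_type not in ("raw", "standardized"):
            raise ValueError("data_type must be 'raw' or 'standardized'")
        if not self.means.index.equals(self.clinical.index):
            raise ValueError("means and clinical must share the patient index")
        if self.means.isna().any().any():
            raise ValueError("marker means contain missing values")

    def markers(self, compartment: str) -> list[str]:
        suffix = f"__{compartment}"
        return sorted(c[: -len(suffix)] for c in self.means.columns if c.endswith(suffix))

    def feature_columns(self, compartment: str | None = None) -> list[str]:
        if compartment is None:
            return list(self.means.columns)
        return [c for c in self.means.columns if c.endswith(f"__{compartment}")]

    @property
    def labels(self) -> pd.Series:
        return self.clinical["label"]

    def standardized(self) -> "PathologyTable":
        """Per-marker z-score over the combined cohorts."""
        z = (self.means - self.means.mean()) / self.means.std(ddof=0).replace(0, 1.0)
        return PathologyTable(self.clinical, z, self.cores, data_type="standardized")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _balanced_labels(n: int, balance: float, rng: np.random.Generator) -> np.ndarray:
    n_r = int(round(n * balance))
    labels = np.array([1] * n_r + [0] * (n - n_r))
    rng.shuffle(labels)
    return labels


def generate_cohorts(spec: CohortSimSpec) -> tuple[list[ExpressionCohort], GroundTruth]:
    """Simulate the multicohort expression matrices.

    Informative genes carry a standardized mean shift ``effect_size``
    between R and NR samples on the latent Gaussian scale; cohort
    location/scale distortions are applied afterwards, and the lognormal
    shape (if requested) is obtained by exponentiation last, so the
    planted class separation is preserved within each cohort up to a
    monotone transform.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    informative = sorted(rng.choice(spec.n_genes, size=spec.n_informative, replace=False))
    informative_genes = [genes[i] for i in informative]
    shifts = spec._per_cohort(spec.cohort_shift)
    scales = spec._per_cohort(spec.cohort_scale)

    cohorts, latent = [], {}
    for cid, n, shift, scale in zip(spec.ids(), spec.cohort_sizes, shifts, scales):
        truth = _balanced_labels(n, spec.class_balance, rng)
        x = rng.normal(0.0, 1.0, size=(spec.n_genes, n))
        x[informative, :] += spec.effect_size * truth[None, :]
        x = x * scale + shift
        if spec.shape == "lognormal":
            x = np.exp(x)
        labels = truth.copy()
        if spec.label_noise > 0:
            flips = rng.random(n) < spec.label_noise
            labels[flips] = 1 - labels[flips]
        samples = [f"{cid}_S{j:03d}" for j in range(n)]
        cohorts.append(ExpressionCohort(
            values=pd.DataFrame(x, index=genes, columns=samples),
            labels=pd.Series(labels, index=samples),
            cohort_id=cid,
        ))
        latent[cid] = truth.tolist()

    return cohorts, GroundTruth(informative_genes=informative_genes, latent_response=latent)


def _uniform_censor_bound(hazards: np.ndarray, censor_rate: float) -> float:
    """Upper bound b of Uniform(0, b) censoring giving the target censored
    fraction for a mixture of exponential event times."""

    def censored_fraction(b: float) -> float:
        lam_b = hazards * b
        return float(np.mean((1.0 - np.exp(-lam_b)) / lam_b))

    lo, hi = 1e-9, 1e9
    return brentq(lambda b: censored_fraction(b) - censor_rate, lo, hi)


def simulate_survival(latent_response: np.ndarray, hazard_ratio: float,
                      censor_rate: float, baseline_hazard: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times with proportional hazards and independent
    uniform censoring.

    Responders (latent 1) have hazard ``baseline_hazard``; nonresponders
    have ``baseline_hazard * hazard_ratio``.  Returns (time, event).
    """
    latent = np.asarray(latent_response, dtype=int)
    hazards = np.where(latent == 1, baseline_hazard, baseline_hazard * hazard_ratio)
    t = rng.exponential(1.0 / hazards)
    if censor_rate <= 0:
        return t, np.ones_like(latent)
    b = _uniform_censor_bound(hazards, censor_rate)
    c = rng.uniform(0.0, b, size=len(latent))
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    return time, event


_SUBTYPES = ("LumP", "LumU", "Ba/Sq")
_SUBTYPE_PROBS = (18 / 39, 10 / 39, 11 / 39)   # observed consensus-subtype mix


def generate_pathology(spec: PathologySimSpec) -> tuple[PathologyTable, GroundTruth]:
    """Simulate the two-compartment digital-pathology marker table.

    Intensities are lognormal (DAB optical densities are positive and
    right-skewed); predictive markers in each compartment carry a mean
    shift ``effect_size`` on the log scale between latent responders and
    nonresponders.  Each patient contributes ``cores_per_patient``
    replicate cores whose mean is the working value.  OS and PFS times
    follow exponential proportional-hazards models coupled to the latent
    response.
    """
    rng = np.random.default_rng(spec.seed)
    markers = [f"M{i:02d}" for i in range(spec.n_markers)]
    predictive = {
        comp: sorted(rng.choice(markers, size=spec.n_predictive, replace=False).tolist())
        for comp in ("tumor", "stroma")
    }

    rows_clin, core_rows, mean_rows = [], [], []
    latent_all = {}
    for cohort, n, balance in zip(("NAC", "PCT"), spec.n_patients, spec.class_balance):
        truth = _balanced_labels(n, balance, rng)
        patients = [f"{cohort}_P{j:03d}" for j in range(n)]
        latent_all[cohort] = truth.tolist()

        os_time, os_event = simulate_survival(truth, spec.hazard_ratio,
                                              spec.censor_rate, spec.baseline_hazard, rng)
        pfs_time, pfs_event = simulate_survival(truth, spec.hazard_ratio,
                                                spec.censor_rate, 1.5 * spec.baseline_hazard, rng)
        subtype = rng.choice(_SUBTYPES, size=n, p=_SUBTYPE_PROBS)
        for i, pid in enumerate(patients):
            rows_clin.append({
                "patient": pid, "cohort": cohort, "label": int(truth[i]),
                "subtype": subtype[i],
                "os_time": float(os_time[i]), "os_event": int(os_event[i]),
                "pfs_time": float(pfs_time[i]), "pfs_event": int(pfs_event[i]),
            })

        for comp in ("tumor", "stroma"):
            base = rng.normal(0.0, 1.0, size=(n, spec.n_markers))
            idx = [markers.index(m) for m in predictive[comp]]
            base[:, idx] += spec.effect_size * truth[:, None]
            # replicate cores around each patient's latent log-intensity
            cores = base[:, :, None] + rng.normal(
                0.0, spec.core_sd, size=(n, spec.n_markers, spec.cores_per_patient))
            intensity = np.exp(cores)
            means = intensity.mean(axis=2)
            for i, pid in enumerate(patients):
                mean_rows.append({"patient": pid, **{
                    f"{m}__{comp}": means[i, k] for k, m in enumerate(markers)}})
                for k, m in enumerate(markers):
                    for c in range(spec.cores_per_patient):
                        core_rows.append({"patient": pid, "marker": m,
                                          "compartment": comp, "core": c,
                                          "value": float(intensity[i, k, c])})

    clinical = pd.DataFrame(rows_clin).set_index("patient")
    # one row per (patient, compartment); .first() skips the NaNs of the
    # other compartment's columns, merging the two rows per patient
    means = pd.DataFrame(mean_rows).groupby("patient").first().loc[clinical.index]
    cores = pd.DataFrame(core_rows)
    table = PathologyTable(clinical=clinical, means=means, cores=cores, data_type="raw")
    truth = GroundTruth(
        predictive_markers=predictive, latent_response=latent_all,
        hazard_params={"baseline_hazard": spec.baseline_hazard,
                       "hazard_ratio": spec.hazard_ratio},
    )
    return table, truth


def synthetic_classifier_sets(genes: list[str], n_sets: int = 17,
                              sizes: list[int] | None = None,
                              seed: int = 0) -> list[GeneClassifier]:
    """Random gene sets standing in for published literature classifiers.

    Synthetic: sizes default to a spread typical of published subtyping
    signatures (8-60 genes); membership is drawn at random from the
    simulated gene namespace and carries no biological meaning.
    """
    rng = np.random.default_rng(seed)
    if sizes is None:
        sizes = [int(s) for s in rng.integers(8, 61, size=n_sets)]
    if len(sizes) != n_sets:
        raise ValueError("sizes length must equal n_sets")
    out = []
    for i, size in enumerate(sizes):
        members = sorted(rng.choice(genes, size=min(size, len(genes)), replace=False))
        out.append(GeneClassifier(name=f"synthetic_classifier_{i + 1:02d}",
                                  genes=list(members), provenance="literature"))
    return out


# ---------------------------------------------------------------------------
# fixture I/O (plain-text TSV / GMT / JSON; lossless round trips)
# ---------------------------------------------------------------------------

def write_expression_tsv(cohort: ExpressionCohort, matrix_path, labels_path) -> None:
    df = cohort.values.copy()
    df.index.name = "gene"
    df.to_csv(matrix_path, sep="\t", float_format="%.17g")
    labels = pd.DataFrame({
        "sample": cohort.labels.index,
        "cohort": cohort.cohort_id,
        "label": cohort.labels.to_numpy(dtype=int),
    })
    labels.to_csv(labels_path, sep="\t", index=False)


def read_expression_tsv(matrix_path, labels_path) -> ExpressionCohort:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0,
                         float_precision="round_trip")
    labels = pd.read_csv(labels_path, sep="\t")
    cohort_id = str(labels["cohort"].iloc[0])
    series = pd.Series(labels["label"].to_numpy(dtype=int),
                       index=labels["sample"].astype(str))
    return ExpressionCohort(values=values, labels=series.loc[values.columns],
                            cohort_id=cohort_id)


def write_gmt(classifiers: list[GeneClassifier], path) -> None:
    with open(path, "w") as fh:
        for clf in classifiers:
            fh.write("\t".join([clf.name, clf.provenance, *clf.genes]) + "\n")


def read_gmt(path) -> list[GeneClassifier]:
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out.append(GeneClassifier(name=parts[0], genes=parts[2:],
                                      provenance=parts[1] or "literature"))
    return out


def write_pathology(table: PathologyTable, means_path, cores_path) -> None:
    wide = table.clinical.join(table.means)
    wide.index.name = "patient"
    wide.to_csv(means_path, sep="\t", float_format="%.17g")
    table.cores.to_csv(cores_path, sep="\t", index=False, float_format="%.17g")


def read_pathology(means_path, cores_path, data_type: str = "raw") -> PathologyTable:
    wide = pd.read_csv(means_path, sep="\t", index_col="patient",
                       float_precision="round_trip")
    clin_cols = ["cohort", "label", "subtype", "os_time", "os_event",
                 "pfs_time", "pfs_event"]
    clinical = wide[[c for c in clin_cols if c in wide.columns]]
    means = wide[[c for c in wide.columns if "__" in c]]
    cores = pd.read_csv(cores_path, sep="\t", float_precision="round_trip")
    return PathologyTable(clinical=clinical, means=means, cores=cores, data_type=data_type)


def write_fixture(cohorts: list[ExpressionCohort], pathology: PathologyTable | None,
                  truth: GroundTruth, out_dir,
                  classifiers: list[GeneClassifier] | None = None) -> dict[str, Path]:
    """Write a complete plain-text fixture set and return the file map."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {out}: {exc}") from exc
    files: dict[str, Path] = {}
    for cohort in cohorts:
        m = out / f"{cohort.cohort_id}_expression.tsv"
        l = out / f"{cohort.cohort_id}_labels.tsv"
        write_expression_tsv(cohort, m, l)
        files[f"{cohort.cohort_id}_expression"] = m
        files[f"{cohort.cohort_id}_labels"] = l
    if classifiers:
        g = out / "classifiers.gmt"
        write_gmt(classifiers, g)
        files["classifiers"] = g
    if pathology is not None:
        pm, pc = out / "pathology_means.tsv", out / "pathology_cores.tsv"
        write_pathology(pathology, pm, pc)
        files["pathology_means"], files["pathology_cores"] = pm, pc
    gt = out / "ground_truth.json"
    gt.write_text(json.dumps(truth.to_dict(), indent=2))
    files["ground_truth"] = gt
    return files
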