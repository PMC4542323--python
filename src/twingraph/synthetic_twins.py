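"""Synthetic twin cohorts with known genetic/environmental covariance.

The generator draws multivariate-normal phenotypes for monozygotic (MZ) and
dizygotic (DZ) twin pairs under the classical biometric model: additive
genetic deviates correlate 1.0 across MZ co-twins and 0.5 across DZ co-twins,
shared-environment deviates are identical within every pair, and
unique-environment deviates are independent per individual.  Because the
population A/C/E covariance matrices are inputs, every downstream fit has
ground truth for parameter-recovery and calibration tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Region abbreviations for the 12 genetically derived parcellations per
#: hemisphere (motor-premotor/central, occipital, postlateral temporal,
#: superior parietal, orbitofrontal, superior temporal, inferior parietal,
#: dorsomedial frontal, anteromedial temporal, precuneus, dorsolateral
#: prefrontal, pars opercularis).
REGION_ABBREVIATIONS = (
    "C", "O", "PLT", "SP", "OF", "ST",
    "IP", "DMF", "AMT", "PRC", "DLP", "PRS",
)

#: Full region names keyed by abbreviation.
REGION_NAMES = {
    "C": "Motor-Premotor",
    "O": "Occipital",
    "PLT": "Postlateral temporal",
    "SP": "Superior parietal",
    "OF": "Orbitofrontal",
    "ST": "Superior temporal",
    "IP": "Inferior parietal",
    "DMF": "Dorsomedial frontal",
    "AMT": "Anteromedial temporal",
    "PRC": "Precuneus",
    "DLP": "Dorsolateral prefrontal",
    "PRS": "Pars opercularis",
}

COVARIATE_COLUMNS = ("age", "scanner", "global_measure")

_PSD_TOL = 1e-8


def _check_psd(name: str, mat: np.ndarray, p: int) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (p, p):
        raise ValueError(f"{name} must be {p}x{p}, got {mat.shape}")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError(f"{name} is not symmetric")
    eigs = np.linalg.eigvalsh(mat)
    if eigs.min() < -_PSD_TOL:
        raise ValueError(
            f"{name} is not positive semidefinite (min eigenvalue {eigs.min():.3g})"
        )
    return mat


def _psd_sqrt(mat: np.ndarray) -> np.ndarray:
    """Symmetric square root; tolerates semidefinite input."""
    w, v = np.linalg.eigh(mat)
    w = np.clip(w, 0.0, None)
    return v @ np.diag(np.sqrt(w)) @ v.T


@dataclass
class SimulationSpec:
    """Population parameters for a simulated twin cohort.

    ``A_cov``, ``C_cov`` and ``E_cov`` are the P x P additive-genetic,
    shared-environment and unique-environment covariance matrices of the
    P phenotypes; each must be symmetric positive semidefinite.
    ``covariate_effects`` maps covariate name (age, scanner, global_measure)
    to a length-P slope vector added linearly to the phenotypes.
    """

    n_mz_pairs: int
    n_dz_pairs: int
    phenotype_labels: Sequence[str]
    A_cov: np.ndarray
    C_cov: np.ndarray | None = None
    E_cov: np.ndarray | None = None
    n_singletons: int = 0
    covariate_effects: Mapping[str, np.ndarray] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        p = len(self.phenotype_labels)
        if p < 1:
            raise ValueError("at least one phenotype label required")
        if len(set(self.phenotype_labels)) != p:
            raise ValueError("phenotype labels must be unique")
        if self.C_cov is None:
            self.C_cov = np.zeros((p, p))
        if self.E_cov is None:
            self.E_cov = np.eye(p)
        self.A_cov = _check_psd("A_cov", self.A_cov, p)
        self.C_cov = _check_psd("C_cov", self.C_cov, p)
        self.E_cov = _check_psd("E_cov", self.E_cov, p)
        for n in (self.n_mz_pairs, self.n_dz_pairs, self.n_singletons):
            if n < 0:
                raise ValueError("counts must be nonnegative")
        if self.n_mz_pairs + self.n_dz_pairs < 1:
            raise ValueError("need at least one MZ or DZ family")
        for name, slopes in self.covariate_effects.items():
            if name not in COVARIATE_COLUMNS:
                raise ValueError(f"unknown covariate {name!r}")
            slopes = np.asarray(slopes, dtype=float)
            if slopes.shape != (p,):
                raise ValueError(f"covariate_effects[{name!r}] must have length {p}")

    @property
    def n_phenotypes(self) -> int:
        return len(self.phenotype_labels)

    def to_json(self) -> str:
        d = {
            "n_mz_pairs": self.n_mz_pairs,
            "n_dz_pairs": self.n_dz_pairs,
            "n_singletons": self.n_singletons,
            "phenotype_labels": list(self.phenotype_labels),
            "A_cov": np.asarray(self.A_cov).tolist(),
            "C_cov": np.asarray(self.C_cov).tolist(),
            "E_cov": np.asarray(self.E_cov).tolist(),
            "covariate_effects": {
                k: np.asarray(v).tolist() for k, v in self.covariate_effects.items()
            },
            "seed": self.seed,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationSpec":
        d = json.loads(text)
        return cls(
            n_mz_pairs=d["n_mz_pairs"],
            n_dz_pairs=d["n_dz_pairs"],
            n_singletons=d.get("n_singletons", 0),
            phenotype_labels=d["phenotype_labels"],
            A_cov=np.asarray(d["A_cov"], dtype=float),
            C_cov=np.asarray(d["C_cov"], dtype=float),
            E_cov=np.asarray(d["E_cov"], dtype=float),
            covariate_effects={
                k: np.asarray(v, dtype=float)
                for k, v in d.get("covariate_effects", {}).items()
            },
            seed=d.get("seed", 0),
        )


@dataclass
class TwinCohort:
    """Long-format twin cohort: one row per observed individual.

    Columns: family_id, member_index (1 or 2), zygosity (MZ/DZ), the
    covariates (age, scanner, global_measure), then one column per phenotype.
    Missing phenotype entries are NaN; a fully unobserved co-twin simply has
    no row.
    """

    data: pd.DataFrame
    phenotype_labels: list[str]

    def __post_init__(self) -> None:
        required = {"family_id", "member_index", "zygosity"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"cohort data missing columns: {sorted(missing)}")
        bad = set(self.data["zygosity"].unique()) - {"MZ", "DZ"}
        if bad:
            raise ValueError(f"unsupported zygosity codes: {sorted(bad)}")
        absent = [p for p in self.phenotype_labels if p not in self.data.columns]
        if absent:
            raise ValueError(f"phenotype columns absent from data: {absent}")
        sizes = self.data.groupby("family_id").size()
        if (sizes > 2).any():
            raise ValueError("families with more than two members are not twin pairs")
        if (sizes < 1).any():  # pragma: no cover - groupby cannot yield empty
            raise ValueError("every family must have at least one observed member")

    @property
    def n_families(self) -> int:
        return self.data["family_id"].nunique()

    def families_by_zygosity(self, zygosity: str) -> pd.DataFrame:
        return self.data[self.data["zygosity"] == zygosity]

    def complete_pairs(self, zygosity: str) -> pd.DataFrame:
        """Wide table of families of the given zygosity with both members."""
        sub = self.families_by_zygosity(zygosity)
        counts = sub.groupby("family_id").size()
        full = counts[counts == 2].index
        return sub[sub["family_id"].isin(full)]

    def cross_twin_correlation(self, phenotype: str, zygosity: str) -> float:
        """Empirical double-entered cross-twin correlation for one phenotype."""
        sub = self.complete_pairs(zygosity).sort_values(["family_id", "member_index"])
        y1 = sub[sub["member_index"] == 1][phenotype].to_numpy()
        y2 = sub[sub["member_index"] == 2][phenotype].to_numpy()
        ok = ~(np.isnan(y1) | np.isnan(y2))
        y1, y2 = y1[ok], y2[ok]
        # double entry symmetrizes the estimate under twin exchangeability
        a = np.concatenate([y1, y2])
        b = np.concatenate([y2, y1])
        return float(np.corrcoef(a, b)[0, 1])

    def to_csv(self, path: str | Path) -> None:
        cols = ["family_id", "member_index", "zygosity", *COVARIATE_COLUMNS,
                *self.phenotype_labels]
        present = [c for c in cols if c in self.data.columns]
        self.data[present].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path,
                 phenotype_labels: Sequence[str] | None = None) -> "TwinCohort":
        df = pd.read_csv(path)
        if phenotype_labels is None:
            skip = {"family_id", "member_index", "zygosity", *COVARIATE_COLUMNS}
            phenotype_labels = [c for c in df.columns if c not in skip]
        return cls(df, list(phenotype_labels))


def plan_parcellation_panel(
    n_per_hemisphere: int = 12,
    measures: Sequence[str] = ("SA", "CT"),
) -> list[str]:
    """Label panel of hemisphere x measure x region phenotype names.

    Labels follow the ``{L|R}-{region}-{SA|CT}`` scheme, e.g. ``L-C-SA`` or
    ``R-DLP-CT``.  The default (12 regions per hemisphere, both measures)
    reproduces the 48-measure panel of 24 regional surface-area and 24
    regional mean-thickness phenotypes.
    """
    if n_per_hemisphere < 1:
        raise ValueError("n_per_hemisphere must be >= 1")
    if n_per_hemisphere > len(REGION_ABBREVIATIONS):
        raise ValueError(
            f"at most {len(REGION_ABBREVIATIONS)} regions per hemisphere available"
        )
    for m in measures:
        if m not in ("SA", "CT"):
            raise ValueError(f"unknown measure {m!r}; expected SA or CT")
    regions = REGION_ABBREVIATIONS[:n_per_hemisphere]
    return [
        f"{hemi}-{region}-{measure}"
        for measure in measures
        for hemi in ("L", "R")
        for region in regions
    ]


def parse_label(label: str) -> tuple[str, str, str]:
    """Split a panel label into (hemisphere, region, measure)."""
    parts = label.split("-")
    if len(parts) != 3 or parts[0] not in ("L", "R") or parts[2] not in ("SA", "CT"):
        raise ValueError(f"label {label!r} does not follow the L-REGION-SA scheme")
    return parts[0], parts[1], parts[2]


def generate_cohort(spec: SimulationSpec) -> TwinCohort:
    """Draw a twin cohort from the biometric model defined by ``spec``.

    MZ co-twins share one additive-genetic draw; DZ co-twins decompose the
    genetic deviate as g = g_common + g_own with Var(g_common) =
    Var(g_own) = A/2, giving the model-implied cross-twin genetic
    correlation of 0.5 component-wise.  C deviates are shared within every
    family; E deviates are independent per individual.  Singleton families
    are generated as pairs (alternating MZ/DZ) with one member dropped at
    random, so the retained twin still reflects familial structure.
    Deterministic for a fixed spec and seed.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.n_phenotypes
    sqA = _psd_sqrt(spec.A_cov)
    sqAh = _psd_sqrt(0.5 * spec.A_cov)
    sqC = _psd_sqrt(spec.C_cov)
    sqE = _psd_sqrt(spec.E_cov)

    # singleton families split alternately between zygosities
    n_single_mz = (spec.n_singletons + 1) // 2
    n_single_dz = spec.n_singletons // 2

    rows: list[dict] = []
    fam = 0

    def draw_pair(zygosity: str, keep_both: bool) -> None:
        nonlocal fam
        fam += 1
        if zygosity == "MZ":
            g = rng.standard_normal(p) @ sqA
            g1, g2 = g, g
        else:
            gc = rng.standard_normal(p) @ sqAh
            g1 = gc + rng.standard_normal(p) @ sqAh
            g2 = gc + rng.standard_normal(p) @ sqAh
        c = rng.standard_normal(p) @ sqC
        age = rng.uniform(51.0, 60.0)
        scanner = float(rng.integers(0, 2))
        members = (1, 2) if keep_both else (int(rng.integers(1, 3)),)
        for idx, g in ((1, g1), (2, g2)):
            if idx not in members:
                continue
            e = rng.standard_normal(p) @ sqE
            y = g + c + e
            global_measure = rng.standard_normal()
            cov_vals = {"age": age, "scanner": scanner,
                        "global_measure": global_measure}
            for name, slopes in spec.covariate_effects.items():
                y = y + np.asarray(slopes, dtype=float) * cov_vals[name]
            row = {
                "family_id": f"F{fam:05d}",
                "member_index": idx,
                "zygosity": zygosity,
                **cov_vals,
            }
            row.update(dict(zip(spec.phenotype_labels, y)))
            rows.append(row)

    for _ in range(spec.n_mz_pairs):
        draw_pair("MZ", keep_both=True)
    for _ in range(spec.n_dz_pairs):
        draw_pair("DZ", keep_both=True)
    for _ in range(n_single_mz):
        draw_pair("MZ", keep_both=False)
    for _ in range(n_single_dz):
        draw_pair("DZ", keep_both=False)

    df = pd.DataFrame(rows)
    return TwinCohort(df, list(spec.phenotype_labels))


def bilateral_block_cov(
    labels: Sequence[str],
    diag: float = 0.5,
    homologue_r: float = 0.8,
    background_r: float = 0.0,
) -> np.ndarray:
    """Covariance matrix with elevated correlation between L/R homologues.

    ``diag`` is the per-phenotype variance; homologous regions (same region
    and measure, opposite hemisphere) get correlation ``homologue_r`` and
    every other pair ``background_r``.  Raises if the result is not PSD.
    """
    p = len(labels)
    parsed = [parse_label(lab) for lab in labels]
    mat = np.full((p, p), background_r * diag)
    for i in range(p):
        mat[i, i] = diag
        for j in range(i + 1, p):
            hi, ri, mi = parsed[i]
            hj, rj, mj = parsed[j]
            if ri == rj and mi == mj and hi != hj:
                mat[i, j] = mat[j, i] = homologue_r * diag
    return _check_psd("bilateral block covariance", mat, p)


def demo_spec(
    n_mz_pairs: int = 100,
    n_dz_pairs: int = 70,
    n_singletons: int = 89,
    n_regions: int = 3,
    measures: Sequence[str] = ("SA",),
    a2: float = 0.5,
    homologue_rg: float = 0.8,
    seed: int = 0,
) -> SimulationSpec:
    """Small ready-made spec: bilateral panel, heritability ``a2``, AE model.

    Default family counts mirror a midlife twin cohort of 100 MZ pairs,
    70 DZ pairs and 89 unpaired twins; phenotypes are standardized so the
    additive-genetic variance equals the heritability.
    """
    labels = plan_parcellation_panel(n_regions, measures)
    A = bilateral_block_cov(labels, diag=a2, homologue_r=homologue_rg)
    E = np.eye(len(labels)) * (1.0 - a2)
    effects = {
        "age": np.full(len(labels), 0.02),
        "scanner": np.full(len(labels), 0.1),
        "global_measure": np.full(len(labels), 0.3),
    }
    return SimulationSpec(
        n_mz_pairs=n_mz_pairs,
        n_dz_pairs=n_dz_pairs,
        n_singletons=n_singletons,
        phenotype_labels=labels,
        A_cov=A,
        C_cov=np.zeros((len(labels), len(labels))),
        E_cov=E,
        covariate_effects=effects,
        seed=seed,
    )
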