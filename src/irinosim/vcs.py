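"""Virtual clinical studies (VCS).

One VCS replicate generates a virtual population, simulates every patient,
assigns side effects by an exposure rank rule — the ``n_neutropenia``
highest unbound plasma SN-38 AUCs develop neutropenia and the ``n_diarrhea``
highest unbound enterocyte SN-38 AUCs develop diarrhea — and runs the
association battery:

* category I  — Welch's t test (Bonferroni-corrected within locus) of the
  dose-normalized SN-38 plasma concentration at end of infusion against
  UGT1A1*28 and SLCO1B1 c.521T>C diplotypes;
* categories II/III — Fisher's exact test of each side effect against each
  of the six loci under dominant and recessive genetic codings;
* category IV — Wilcoxon rank-sum of the biliary index
  (AUC_irinotecan * AUC_SN-38 / AUC_SN-38G) between patients with and
  without diarrhea.

Replicating the study many times yields the *reproduction frequency* of
each association — how often a study of that size would have found the
effect — which is the Monte-Carlo analogue of statistical power.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .model import IrinotecanPBPK
from .population import GENOTYPE_LOCI, PopulationModel, VirtualPatient

__all__ = [
    "VCSConfig",
    "ReplicateOutcome",
    "VCSResults",
    "VirtualClinicalStudy",
    "assign_side_effects",
    "test_concentration_by_genotype",
    "test_side_effect_by_genotype",
    "test_biliary_index",
    "CRITERIA_THRESHOLDS",
]

#: reproduction-count thresholds of the seven selection criteria
#: (out of 100 replicates)
CRITERIA_THRESHOLDS = {
    "UGT1A1*28 het vs C90": 75,
    "UGT1A1*28 hom vs C90": 75,
    "UGT1A1*28 vs neutropenia": 75,
    "UGT1A1*28 vs diarrhea": 25,
    "SLCO1B1_521 vs C90": 25,
    "SLCO1B1_521 vs neutropenia": 25,
    "biliary index vs diarrhea": 25,
}


@dataclass
class VCSConfig:
    """Study design of one virtual clinical study."""

    n_patients: int = 127
    n_replicates: int = 100
    n_neutropenia: int = 21
    n_diarrhea: int = 8
    alpha: float = 0.05
    log_scale: bool = False  # compare log C90/dose instead of linear
    require_direction: bool = True  # significance must have the clinical sign

    def __post_init__(self) -> None:
        if self.n_neutropenia > self.n_patients or self.n_diarrhea > self.n_patients:
            raise ValueError("side-effect counts cannot exceed population size")

    def scaled_counts(self, n: int) -> tuple[int, int]:
        """Side-effect counts for a population of size ``n`` (proportional
        to the 21/127 and 8/127 reference incidences)."""
        return (
            max(1, round(self.n_neutropenia * n / 127)),
            max(1, round(self.n_diarrhea * n / 127)),
        )


# ----------------------------------------------------------------------
# statistical tests
# ----------------------------------------------------------------------
def _welch(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or len(b) < 2:
        return np.nan
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return np.nan
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def test_concentration_by_genotype(
    values: np.ndarray, genotypes: np.ndarray
) -> dict[str, tuple[float, float]]:
    """Pairwise Welch tests wild-vs-het and wild-vs-hom within one locus.

    Returns ``{"het": (p_adj, direction), "hom": (p_adj, direction)}`` where
    p is Bonferroni-adjusted for the two comparisons and direction is the
    sign of (variant mean - wild mean).  A comparison with fewer than two
    patients in either group is not evaluable (NaN).
    """
    values = np.asarray(values, dtype=float)
    genotypes = np.asarray(genotypes)
    wild = values[genotypes == "wild"]
    out = {}
    for g in ("het", "hom"):
        grp = values[genotypes == g]
        p = _welch(wild, grp)
        p_adj = min(1.0, 2.0 * p) if np.isfinite(p) else np.nan
        direction = (
            float(np.sign(grp.mean() - wild.mean()))
            if len(grp) and len(wild)
            else np.nan
        )
        out[g] = (p_adj, direction)
    return out


def test_side_effect_by_genotype(
    flags: np.ndarray, genotypes: np.ndarray, model: str
) -> tuple[float, float]:
    """Two-sided Fisher exact p for a side effect under a genetic model.

    ``dominant`` codes het+hom as carriers; ``recessive`` codes hom only.
    Returns (p, direction) with direction the sign of the carrier-vs-rest
    difference in side-effect rate; degenerate margins are not evaluable.
    """
    if model not in ("dominant", "recessive"):
        raise ValueError("model must be 'dominant' or 'recessive'")
    flags = np.asarray(flags, dtype=bool)
    genotypes = np.asarray(genotypes)
    carrier = (
        np.isin(genotypes, ("het", "hom")) if model == "dominant"
        else genotypes == "hom"
    )
    table = np.array(
        [
            [np.sum(carrier & flags), np.sum(carrier & ~flags)],
            [np.sum(~carrier & flags), np.sum(~carrier & ~flags)],
        ]
    )
    if table.sum(axis=1).min() == 0 or flags.all() or not flags.any():
        return np.nan, np.nan
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    rate_c = table[0, 0] / table[0].sum()
    rate_n = table[1, 0] / table[1].sum()
    return p, float(np.sign(rate_c - rate_n))


def test_biliary_index(
    index_values: np.ndarray, diarrhea_flags: np.ndarray
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum of biliary index by diarrhea status.

    Exact enumeration for small groups without ties, normal approximation
    with tie correction otherwise.  Returns (p, direction).
    """
    index_values = np.asarray(index_values, dtype=float)
    diarrhea_flags = np.asarray(diarrhea_flags, dtype=bool)
    a = index_values[diarrhea_flags]
    b = index_values[~diarrhea_flags]
    if len(a) == 0 or len(b) == 0:
        return np.nan, np.nan
    method = "exact" if max(len(a), len(b)) <= 25 else "asymptotic"
    p = float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )
    return p, float(np.sign(np.median(a) - np.median(b)))


def assign_side_effects(
    plasma_unbound_auc: np.ndarray,
    enterocyte_unbound_auc: np.ndarray,
    n_neutropenia: int,
    n_diarrhea: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Top-k exposure rank rule; ties broken by (lower) patient index."""
    n = len(plasma_unbound_auc)
    if n_neutropenia > n or n_diarrhea > n:
        raise ValueError("cannot flag more patients than exist")

    def top_k(values: np.ndarray, k: int) -> np.ndarray:
        flags = np.zeros(len(values), dtype=bool)
        if k > 0:
            order = np.lexsort((np.arange(len(values)), -np.asarray(values)))
            flags[order[:k]] = True
        return flags

    return (
        top_k(plasma_unbound_auc, n_neutropenia),
        top_k(enterocyte_unbound_auc, n_diarrhea),
    )


# ----------------------------------------------------------------------
# replicate engine
# ----------------------------------------------------------------------
@dataclass
class ReplicateOutcome:
    """All association p-values and assignments of one VCS replicate."""

    pvalues: dict[str, float]
    directions: dict[str, float]
    neutropenia: np.ndarray
    diarrhea: np.ndarray
    exposures: pd.DataFrame  # per patient: genotypes + exposure metrics
    seed: int


def _expected_direction(assoc: str) -> float:
    """Clinically expected sign of each association.

    Reduced-function variants raise SN-38 exposure and side-effect risk,
    and a high biliary index accompanies diarrhea, so every tabulated
    association is expected positive.
    """
    return 1.0


class VirtualClinicalStudy:
    """VCS engine for one parameter set (statsmodels-style model object).

    Parameters
    ----------
    population
        A :class:`~irinosim.population.PopulationModel` wrapping the
        parameter set under study plus variability/genetics tables.
    config
        Study design (population size, replicate count, rank-rule counts).
    """

    def __init__(self, population: PopulationModel, config: VCSConfig | None = None):
        self.population = population
        self.config = config or VCSConfig()

    # -- single replicate ------------------------------------------------
    def simulate_patients(
        self, n: int, rng: np.random.Generator
    ) -> tuple[list[VirtualPatient], pd.DataFrame]:
        """Sample and simulate ``n`` patients.

        A patient whose simulation fails is replaced by a fresh draw, up to
        1% of the population (at least one); beyond that the failure is
        structural and propagates.
        """
        from .model import SimulationError

        patients = self.population.sample_population(n, rng)
        resample_budget = max(1, n // 100)
        rows = []
        for i, pt in enumerate(patients):
            for _ in range(resample_budget + 1):
                try:
                    exp = IrinotecanPBPK(pt.params).exposures()
                    break
                except SimulationError:
                    if resample_budget == 0:
                        raise
                    resample_budget -= 1
                    pt = self.population.sample_patient(rng)
                    patients[i] = pt
            row = {
                "patient": i,
                "dose_mg": pt.dose_mg,
                "c90_sn38": exp.c_end_infusion_plasma["SN38"],
                "c90_sn38_per_dose": exp.c_end_infusion_plasma["SN38"] / pt.dose_mg,
                "auc_plasma_unbound_sn38": exp.auc_plasma_unbound["SN38"],
                "auc_enterocyte_unbound_sn38": exp.auc_enterocyte_unbound["SN38"],
                "biliary_index": exp.biliary_index,
            }
            for locus in GENOTYPE_LOCI:
                row[locus] = pt.genotype[locus]
            rows.append(row)
        return patients, pd.DataFrame(rows)

    def run_replicate(self, seed: int, n: int | None = None) -> ReplicateOutcome:
        cfg = self.config
        n = n or cfg.n_patients
        rng = np.random.default_rng(seed)
        _, df = self.simulate_patients(n, rng)
        k_neut, k_diar = (
            (cfg.n_neutropenia, cfg.n_diarrhea)
            if n == 127
            else cfg.scaled_counts(n)
        )
        neut, diar = assign_side_effects(
            df["auc_plasma_unbound_sn38"].to_numpy(),
            df["auc_enterocyte_unbound_sn38"].to_numpy(),
            k_neut,
            k_diar,
        )
        values = df["c90_sn38_per_dose"].to_numpy()
        if cfg.log_scale:
            values = np.log(values)
        pvals: dict[str, float] = {}
        dirs: dict[str, float] = {}
        for locus in ("UGT1A1*28", "SLCO1B1_521"):
            res = test_concentration_by_genotype(values, df[locus].to_numpy())
            for g, (p, d) in res.items():
                pvals[f"C90_SN38|{locus}|{g}"] = p
                dirs[f"C90_SN38|{locus}|{g}"] = d
        for locus in GENOTYPE_LOCI:
            for model in ("dominant", "recessive"):
                for name, flags in (("neutropenia", neut), ("diarrhea", diar)):
                    p, d = test_side_effect_by_genotype(
                        flags, df[locus].to_numpy(), model
                    )
                    pvals[f"{name}|{locus}|{model}"] = p
                    dirs[f"{name}|{locus}|{model}"] = d
        p, d = test_biliary_index(df["biliary_index"].to_numpy(), diar)
        pvals["diarrhea|biliary_index|wilcoxon"] = p
        dirs["diarrhea|biliary_index|wilcoxon"] = d
        return ReplicateOutcome(pvals, dirs, neut, diar, df, seed)

    # -- many replicates -------------------------------------------------
    def run(
        self, seed: int = 0, n_replicates: int | None = None, n: int | None = None
    ) -> "VCSResults":
        reps = n_replicates or self.config.n_replicates
        outcomes = [self.run_replicate(seed + r, n=n) for r in range(reps)]
        return VCSResults(self, outcomes)

    # -- population-size sweep ------------------------------------------
    def reproduction_frequency_sweep(
        self,
        n_list: tuple[int, ...] = (25, 39, 51, 64, 96, 127, 192, 256, 384, 512, 1024, 1280),
        n_replicates: int = 100,
        seed: int = 0,
    ) -> pd.DataFrame:
        """Frequency of a significant UGT1A1*28 / SLCO1B1 521 effect on the
        dose-normalized SN-38 C90 as a function of population size."""
        if list(n_list) != sorted(n_list):
            raise ValueError("n_list must be sorted ascending")
        rows = []
        for i, n in enumerate(n_list):
            res = self.run(seed=seed + 100_000 * (i + 1), n_replicates=n_replicates, n=n)
            rows.append(
                {
                    "n": n,
                    "freq_ugt1a1": res.locus_concentration_frequency("UGT1A1*28"),
                    "freq_slco1b1": res.locus_concentration_frequency("SLCO1B1_521"),
                }
            )
        return pd.DataFrame(rows)

    # -- large-population probability estimation ------------------------
    def side_effect_probability(
        self,
        n_big: int,
        neutropenia_threshold: float = 26.35,
        diarrhea_threshold: float = 53.60,
        seed: int = 0,
        chunk: int = 2000,
    ) -> tuple[float, float]:
        """Fraction of a large virtual population exceeding fixed unbound
        AUC thresholds (plasma for neutropenia, enterocyte for diarrhea).
        Streams in chunks so the population never resides in memory."""
        rng = np.random.default_rng(seed)
        n_neut = n_diar = done = 0
        while done < n_big:
            m = min(chunk, n_big - done)
            for _ in range(m):
                pt = self.population.sample_patient(rng)
                exp = IrinotecanPBPK(pt.params).exposures()
                n_neut += exp.auc_plasma_unbound["SN38"] > neutropenia_threshold
                n_diar += exp.auc_enterocyte_unbound["SN38"] > diarrhea_threshold
            done += m
        return n_neut / n_big, n_diar / n_big


class VCSResults:
    """Aggregated outcomes of repeated virtual clinical studies."""

    def __init__(self, study: VirtualClinicalStudy, outcomes: list[ReplicateOutcome]):
        self.study = study
        self.outcomes = outcomes
        self.pvalues = pd.DataFrame([o.pvalues for o in outcomes])
        self.directions = pd.DataFrame([o.directions for o in outcomes])

    @property
    def n_replicates(self) -> int:
        return len(self.outcomes)

    def significant(self) -> pd.DataFrame:
        """Boolean frame: p < alpha (and, by default, the clinically
        expected direction); not-evaluable tests count as non-significant."""
        cfg = self.study.config
        sig = self.pvalues < cfg.alpha
        if cfg.require_direction:
            expected = {c: _expected_direction(c) for c in self.pvalues.columns}
            sig &= self.directions.eq(pd.Series(expected))
        return sig.fillna(False)

    def significance_counts(self) -> pd.Series:
        return self.significant().sum()

    def locus_concentration_frequency(self, locus: str) -> float:
        """Fraction of replicates with a significant (correct-direction)
        effect of the locus on dose-normalized C90 in either comparison."""
        sig = self.significant()
        cols = [f"C90_SN38|{locus}|het", f"C90_SN38|{locus}|hom"]
        return float(sig[cols].any(axis=1).mean())

    def criteria(self) -> pd.Series:
        """The seven reproduction criteria, scaled to the replicate count."""
        counts = self.significance_counts()
        sig = self.significant()
        scale = self.n_replicates / 100.0

        def either(*cols) -> int:
            return int(sig[list(cols)].any(axis=1).sum())

        achieved = {
            "UGT1A1*28 het vs C90": counts["C90_SN38|UGT1A1*28|het"],
            "UGT1A1*28 hom vs C90": counts["C90_SN38|UGT1A1*28|hom"],
            "UGT1A1*28 vs neutropenia": either(
                "neutropenia|UGT1A1*28|dominant", "neutropenia|UGT1A1*28|recessive"
            ),
            "UGT1A1*28 vs diarrhea": either(
                "diarrhea|UGT1A1*28|dominant", "diarrhea|UGT1A1*28|recessive"
            ),
            "SLCO1B1_521 vs C90": either(
                "C90_SN38|SLCO1B1_521|het", "C90_SN38|SLCO1B1_521|hom"
            ),
            "SLCO1B1_521 vs neutropenia": either(
                "neutropenia|SLCO1B1_521|dominant",
                "neutropenia|SLCO1B1_521|recessive",
            ),
            "biliary index vs diarrhea": counts["diarrhea|biliary_index|wilcoxon"],
        }
        return pd.Series(
            {
                k: bool(achieved[k] >= CRITERIA_THRESHOLDS[k] * scale)
                for k in CRITERIA_THRESHOLDS
            }
        )

    def n_criteria_met(self) -> int:
        return int(self.criteria().sum())

    def summary(self) -> str:
        counts = self.significance_counts()
        crit = self.criteria()
        lines = [
            "Virtual clinical study results",
            "==============================",
            f"replicates        : {self.n_replicates}",
            f"population size   : {self.study.config.n_patients}",
            f"criteria met      : {int(crit.sum())} / 7",
            "",
            "significance counts (p < %.2f):" % self.study.config.alpha,
            counts.to_string(),
            "",
            "reproduction criteria:",
            crit.to_string(),
        ]
        return "\n".join(lines)


def significance_heatmap(
    studies: dict[int, VCSResults]
) -> pd.DataFrame:
    """Rows = associations, columns = parameter-set IDs, cells = counts of
    significant replicates; mirrors the frequency-of-significance map."""
    if not studies:
        raise ValueError("need at least one parameter set")
    return pd.DataFrame(
        {sid: res.significance_counts() for sid, res in studies.items()}
    )
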