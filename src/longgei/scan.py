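"""Per-SNP likelihood-ratio tests and the scan/comparison pipeline.

For each SNP three nested ML fits give three tests:

* genetic main effect, H0: beta_g = 0 — LRT of Model 1 vs 2, chi2(1);
* GEI effect, H0: beta_ge = 0 given the main effect — Model 2 vs 3, chi2(1);
* joint main + GEI, H0: beta_g = beta_ge = 0 — Model 1 vs 3, chi2(2).

By construction the joint statistic is the sum of the other two.  The Model-1
fit contains no SNP term, so it is cached and shared across SNPs fitted to
the same sample; a SNP with missing dosages shrinks the sample, and then all
three models (including Model 1) are refitted on that reduced sample so each
LRT compares fits to identical data.

Scans are deterministic given the dataset and options.  Comparison reports
mirror the two study questions: method concordance (Pearson correlation of
-log10 P between the Kronecker and hierarchical scans) and the longitudinal
significance gain (fraction of SNPs with smaller P under more visits, plus
threshold counts).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import GenotypeTable, LongitudinalFamilyDataset
from .model import LongitudinalGEIModel, MeanModelSpec, RankDeficiencyError

logger = logging.getLogger(__name__)

__all__ = [
    "lrt",
    "SnpScanResult",
    "ModelOneCache",
    "test_snp",
    "ScanTable",
    "scan",
    "ComparisonReport",
    "compare_methods",
    "compare_visits",
    "SCAN_COLUMNS",
]

#: LRT statistics this far below zero flag an optimizer failure rather than
#: roundoff; smaller negatives are clipped to 0 silently.
NEGATIVE_LRT_FLAG = -1e-3


def lrt(loglik_null: float, loglik_alt: float, df: int) -> tuple[float, float]:
    """Likelihood-ratio statistic 2*(l_alt - l_null), clipped at 0, and its chi2 P."""
    if df <= 0:
        raise ValueError("df must be positive")
    stat = 2.0 * (loglik_alt - loglik_null)
    if stat < NEGATIVE_LRT_FLAG:
        logger.warning("negative LRT statistic %.3g clipped to 0", stat)
    stat = max(stat, 0.0)
    return stat, float(stats.chi2.sf(stat, df))


@dataclass
class SnpScanResult:
    """All three tests for one SNP, plus Model-3 effect estimates."""

    snp_id: str
    maf: float
    n_obs: int
    beta_g: float = np.nan
    se_g_sandwich: float = np.nan
    beta_ge: float = np.nan
    se_ge_sandwich: float = np.nan
    loglik1: float = np.nan
    loglik2: float = np.nan
    loglik3: float = np.nan
    lrt_main: float = np.nan
    p_main: float = np.nan
    lrt_gei: float = np.nan
    p_gei: float = np.nan
    lrt_joint: float = np.nan
    p_joint: float = np.nan
    conv1: bool = False
    conv2: bool = False
    conv3: bool = False
    note: str = ""


class ModelOneCache:
    """Model-1 fits keyed by (structure, set of genotype-dropped individuals)."""

    def __init__(self):
        self._cache: dict[tuple[str, frozenset], object] = {}

    def get(self, structure: str, dropped: frozenset, fit_fn):
        key = (structure, dropped)
        if key not in self._cache:
            self._cache[key] = fit_fn()
        return self._cache[key]


def test_snp(
    dataset: LongitudinalFamilyDataset,
    genotypes: GenotypeTable,
    snp_id: str,
    structure: str = "hlm",
    spec: MeanModelSpec | None = None,
    cache: ModelOneCache | None = None,
    n_starts: int = 3,
) -> SnpScanResult:
    """Fit Models 1-3 for one SNP and return the three LRTs.

    Models 2 and 3 are warm-started from the previous model's covariance
    optimum, falling back to the default multi-start if that fails to
    converge.  Any non-converged model leaves the dependent P-values missing
    but keeps the SNP in the output with flags.
    """
    base = spec or MeanModelSpec()
    dosage = genotypes.dosage(snp_id)
    observed_ids = {r.individual_id for lay in dataset.families.values() for r in lay.records}
    missing_ids = frozenset(
        i for i in observed_ids if i not in dosage.index or np.isnan(dosage.get(i, np.nan))
    )
    data = dataset.drop_individuals(missing_ids) if missing_ids else dataset
    used_ids = observed_ids - missing_ids
    d_used = dosage[dosage.index.isin(used_ids)].dropna()
    maf = float(d_used.sum() / (2 * len(d_used))) if len(d_used) else np.nan

    res = SnpScanResult(snp_id=snp_id, maf=maf, n_obs=0)
    if data.n_families < 2:
        res.note = "fewer than 2 families with genotyped members"
        return res
    res.n_obs = data.n_obs

    if len(d_used) and np.ptp(d_used.to_numpy()) == 0.0:
        res.note = "monomorphic in analysis sample"
        return res

    cache = cache or ModelOneCache()

    def fit1():
        m1 = LongitudinalGEIModel.from_dataset(
            data, MeanModelSpec(1, base.covariates, base.exposure), structure
        )
        return m1.fit(n_starts=n_starts)

    try:
        r1 = cache.get(structure, missing_ids, fit1)
    except (RankDeficiencyError, ValueError) as e:
        res.note = f"model 1 failed: {e}"
        return res
    res.loglik1, res.conv1 = r1.llf, r1.converged

    def fit_nested(model_id, warm):
        m = LongitudinalGEIModel.from_dataset(
            data, MeanModelSpec(model_id, base.covariates, base.exposure),
            structure, snp_dosages=dosage,
        )
        r = m.fit(start_params=warm.theta)
        if not r.converged:
            r2 = m.fit(n_starts=n_starts)
            if r2.converged or r2.llf > r.llf:
                r = r2
        return r

    try:
        r2 = fit_nested(2, r1)
        res.loglik2, res.conv2 = r2.llf, r2.converged
        r3 = fit_nested(3, r2)
        res.loglik3, res.conv3 = r3.llf, r3.converged
    except (RankDeficiencyError, ValueError) as e:
        res.note = f"nested fit failed: {e}"
        return res

    if r3.converged:
        res.beta_g = float(r3.fe_params["G"])
        res.se_g_sandwich = float(r3.bse["G"])
        res.beta_ge = float(r3.fe_params["G:E"])
        res.se_ge_sandwich = float(r3.bse["G:E"])
    if res.conv1 and res.conv2:
        res.lrt_main, res.p_main = lrt(res.loglik1, res.loglik2, 1)
    if res.conv2 and res.conv3:
        res.lrt_gei, res.p_gei = lrt(res.loglik2, res.loglik3, 1)
    if res.conv1 and res.conv3:
        res.lrt_joint, res.p_joint = lrt(res.loglik1, res.loglik3, 2)
    return res


SCAN_COLUMNS = [
    "snp_id", "maf", "n_obs",
    "beta_g", "se_g_sandwich", "beta_ge", "se_ge_sandwich",
    "loglik1", "loglik2", "loglik3",
    "lrt_main", "p_main", "lrt_gei", "p_gei", "lrt_joint", "p_joint",
    "conv1", "conv2", "conv3",
]


@dataclass
class ScanTable:
    """Per-SNP scan results plus the metadata needed to rerun the scan."""

    table: pd.DataFrame
    structure: str
    visit_mode: str = "all"
    metadata: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            meta = {"structure": self.structure, "visit_mode": self.visit_mode, **self.metadata}
            fh.write("# " + json.dumps(meta, sort_keys=True) + "\n")
            self.table.to_csv(fh, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read_tsv(cls, path) -> "ScanTable":
        with open(path) as fh:
            first = fh.readline()
            meta = json.loads(first[1:].strip()) if first.startswith("#") else {}
            df = pd.read_csv(fh if first.startswith("#") else path, sep="\t")
        return cls(
            table=df,
            structure=meta.pop("structure", "unknown"),
            visit_mode=meta.pop("visit_mode", "all"),
            metadata=meta,
        )

    def __len__(self) -> int:
        return len(self.table)

    def plot_against(self, other: "ScanTable", ax=None, test: str = "gei"):
        """Scatter of -log10 P from this scan (x) vs ``other`` (y) with the
        diagonal, the visual used for method-concordance and visit-gain
        comparisons.  Requires matplotlib (``plot`` extra)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = _paired(self, other)
        x = _neglog10(m[f"p_{test}_a"].dropna())
        y = _neglog10(m[f"p_{test}_b"].dropna())
        ax.scatter(x, y, s=12, alpha=0.7)
        lim = max(float(x.max(initial=1.0)), float(y.max(initial=1.0))) * 1.05
        ax.plot([0, lim], [0, lim], lw=1, color="grey")
        ax.set_xlabel(f"-log10 P ({self.structure}, {self.visit_mode})")
        ax.set_ylabel(f"-log10 P ({other.structure}, {other.visit_mode})")
        ax.set_title(f"{test} test")
        return ax


def scan(
    dataset: LongitudinalFamilyDataset,
    genotypes: GenotypeTable,
    structure: str = "hlm",
    snp_ids: Sequence[str] | None = None,
    spec: MeanModelSpec | None = None,
    visit_mode: str = "all",
    progress: bool = False,
) -> ScanTable:
    """Run all three tests for each kept SNP under one covariance structure.

    Apply the HWE filter first and pass the kept ids; failures are recorded
    in the output rather than dropped.
    """
    ids = list(snp_ids) if snp_ids is not None else genotypes.snp_ids
    if not ids:
        logger.warning("empty SNP set; returning empty scan table")
    cache = ModelOneCache()
    rows = []
    for k, snp in enumerate(ids):
        r = test_snp(dataset, genotypes, snp, structure=structure, spec=spec, cache=cache)
        rows.append({c: getattr(r, c) for c in SCAN_COLUMNS})
        if progress:
            logger.info("scanned %s (%d/%d) p_joint=%.3g", snp, k + 1, len(ids), r.p_joint)
    df = pd.DataFrame(rows, columns=SCAN_COLUMNS)
    return ScanTable(
        table=df,
        structure=structure,
        visit_mode=visit_mode,
        metadata={"n_obs": dataset.n_obs, "n_families": dataset.n_families},
    )


# ---------------------------------------------------------------------------
# comparisons
# ---------------------------------------------------------------------------

TESTS = ("main", "gei", "joint")
#: -log10 P is capped here before correlating, so P-value underflow to 0
#: cannot inject infinities
NEGLOG10_CAP = 300.0


def _neglog10(p: pd.Series) -> np.ndarray:
    with np.errstate(divide="ignore"):
        v = -np.log10(p.to_numpy(dtype=float))
    return np.minimum(v, NEGLOG10_CAP)


@dataclass
class ComparisonReport:
    """Concordance / gain summary between two scans over the same SNPs."""

    mode: str  # "methods" | "visits"
    correlations: dict[str, float]
    frac_smaller_b: dict[str, float]
    ties: dict[str, int]
    n_used: dict[str, int]
    threshold_counts: dict[str, dict[str, dict[str, int]]]
    labels: tuple[str, str] = ("a", "b")

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @property
    def min_correlation(self) -> float:
        return min(self.correlations.values())


def _paired(a: ScanTable, b: ScanTable) -> pd.DataFrame:
    if set(a.table.snp_id) != set(b.table.snp_id):
        raise ValueError("scans cover different SNP sets")
    m = a.table.merge(b.table, on="snp_id", suffixes=("_a", "_b"))
    if len(m) != len(a.table):
        raise ValueError("duplicate SNP ids in scan tables")
    return m


def compare_methods(
    scan_a: ScanTable, scan_b: ScanTable, thresholds: Sequence[float] = (1e-5, 1e-6, 1e-7)
) -> ComparisonReport:
    """Pearson correlations of -log10 P between two methods, per test.

    SNPs where either scan failed to produce the P-value are excluded
    pairwise, with the used count reported.
    """
    return _compare(scan_a, scan_b, "methods", thresholds,
                    labels=(scan_a.structure, scan_b.structure))


def compare_visits(
    scan_a: ScanTable, scan_b: ScanTable, thresholds: Sequence[float] = (1e-5, 1e-6, 1e-7)
) -> ComparisonReport:
    """Significance gain of scan_b over scan_a (e.g. 5-visit over 1-visit).

    ``frac_smaller_b`` counts SNPs with *strictly* smaller P in scan_b; ties
    are excluded from the fraction and reported separately.
    """
    return _compare(scan_a, scan_b, "visits", thresholds,
                    labels=(scan_a.visit_mode, scan_b.visit_mode))


def _compare(scan_a, scan_b, mode, thresholds, labels) -> ComparisonReport:
    if labels[0] == labels[1]:
        labels = (f"{labels[0]}_a", f"{labels[1]}_b")
    m = _paired(scan_a, scan_b)
    correlations, frac, ties, n_used = {}, {}, {}, {}
    counts: dict[str, dict[str, dict[str, int]]] = {}
    for t in TESTS:
        pa, pb = m[f"p_{t}_a"], m[f"p_{t}_b"]
        ok = pa.notna() & pb.notna()
        n_used[t] = int(ok.sum())
        xa, xb = _neglog10(pa[ok]), _neglog10(pb[ok])
        if ok.sum() >= 2 and np.std(xa) > 0 and np.std(xb) > 0:
            correlations[t] = float(np.corrcoef(xa, xb)[0, 1])
        else:
            correlations[t] = float("nan")
        tied = int((pa[ok] == pb[ok]).sum())
        ties[t] = tied
        frac[t] = float((pb[ok] < pa[ok]).sum() / ok.sum()) if ok.sum() else float("nan")
        counts[t] = {
            labels[0]: {f"{thr:g}": int((pa[ok] < thr).sum()) for thr in thresholds},
            labels[1]: {f"{thr:g}": int((pb[ok] < thr).sum()) for thr in thresholds},
        }
    return ComparisonReport(
        mode=mode,
        correlations=correlations,
        frac_smaller_b=frac,
        ties=ties,
        n_used=n_used,
        threshold_counts=counts,
        labels=tuple(labels),
    )
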