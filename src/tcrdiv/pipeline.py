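"""Cohort-level orchestration: QC accounting, cohort statistics and the
simulate -> diversity -> MDS -> classify end-to-end run.

The sample sheet mirrors the study design: four groups (MEsa, MEmm, MS, HC)
of female donors, one row per (sample, cell type), with CMV serostatus and a
QC status naming the exclusion reason where a library was dropped.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from . import classify, diversity, embed, simkit

__all__ = [
    "VALID_GROUPS",
    "EXCLUSION_REASONS",
    "Chi2Result",
    "RunConfig",
    "apply_qc_exclusions",
    "cmv_association_test",
    "study_sample_sheet",
    "run_all",
    "simulated_validation",
]

logger = logging.getLogger("tcrdiv")

VALID_GROUPS = ("MEsa", "MEmm", "MS", "HC")
EXCLUSION_REASONS = (
    "insufficient_cells",
    "cross_contamination",
    "insufficient_dna",
    "library_failure",
)
CMV_CATEGORIES = ("Positive", "Negative", "Equivocal")


def study_sample_sheet() -> pd.DataFrame:
    """Sample sheet reproducing the study's cohort accounting.

    160 donors (40 per group), each contributing a CD8 and a CD4 row.  The
    exclusion tallies follow the study: CD8 lost one library to insufficient
    enriched cells and five to cross-contamination (154 retained); CD4 lost
    two to insufficient cells, four to insufficient DNA and six to library
    failure (148 retained).
    """
    rows = []
    for gi, group in enumerate(VALID_GROUPS):
        for i in range(40):
            donor = f"{group}{i + 1:02d}"
            for ct in ("CD8", "CD4"):
                rows.append({"sample_id": f"{donor}.{ct}", "donor": donor,
                             "group": group, "cell_type": ct,
                             "age_bin": "40-49", "cmv_status": "NA",
                             "qc_status": "pass", "exclusion_reason": ""})
    df = pd.DataFrame(rows)

    def exclude(ct, reason, k, start):
        idx = df.index[df.cell_type == ct][start:start + k]
        df.loc[idx, ["qc_status", "exclusion_reason"]] = ["excluded", reason]

    exclude("CD8", "insufficient_cells", 1, 0)
    exclude("CD8", "cross_contamination", 5, 1)
    exclude("CD4", "insufficient_cells", 2, 0)
    exclude("CD4", "insufficient_dna", 4, 2)
    exclude("CD4", "library_failure", 6, 6)
    return df


def apply_qc_exclusions(sheet: pd.DataFrame):
    """Split a sample sheet into retained rows and an exclusion accounting.

    Returns ``(retained, report)`` where the report bins excluded rows by
    reason and gives per-cell-type retained counts; retained + excluded
    equals the input row count for every cell type (conservation).
    """
    sheet = sheet.copy()
    bad = set(sheet.loc[sheet.qc_status == "excluded", "exclusion_reason"]) - set(EXCLUSION_REASONS)
    if bad:
        raise ValueError(f"unknown exclusion reason(s): {sorted(bad)}")
    unknown_groups = set(sheet.group) - set(VALID_GROUPS)
    if unknown_groups:
        raise ValueError(f"unknown group(s): {sorted(unknown_groups)}")
    retained = sheet[sheet.qc_status != "excluded"].copy()
    excluded = sheet[sheet.qc_status == "excluded"]
    report = {
        "n_input": int(len(sheet)),
        "n_retained": int(len(retained)),
        "n_excluded": int(len(excluded)),
        "by_reason": excluded.groupby("exclusion_reason").size().to_dict(),
        "retained_by_cell_type": retained.groupby("cell_type").size().to_dict(),
        "input_by_cell_type": sheet.groupby("cell_type").size().to_dict(),
    }
    assert report["n_retained"] + report["n_excluded"] == report["n_input"]
    return retained, report


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    dof: int
    p_value: float
    table: pd.DataFrame


def cmv_association_test(sheet_or_table) -> Chi2Result:
    """Pearson chi-square test of CMV serostatus against sample group.

    Accepts either a sample sheet (``cmv_status``/``group`` columns; NA rows
    dropped, one row per donor is the caller's responsibility) or a
    precomputed serostatus-by-group contingency table.  No continuity
    correction is applied; all-zero rows/columns are dropped with a warning.
    """
    x = sheet_or_table
    if isinstance(x, pd.DataFrame) and {"cmv_status", "group"} <= set(x.columns):
        known = x[x.cmv_status.isin(CMV_CATEGORIES)]
        table = pd.crosstab(known.cmv_status, known.group)
    else:
        table = pd.DataFrame(x) if not isinstance(x, pd.DataFrame) else x.copy()
    zero_rows = table.index[(table.sum(axis=1) == 0)]
    zero_cols = table.columns[(table.sum(axis=0) == 0)]
    if len(zero_rows) or len(zero_cols):
        warnings.warn("dropping all-zero serostatus rows/columns before testing")
        table = table.drop(index=zero_rows, columns=zero_cols)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least a 2x2 table after dropping empty categories")
    res = chi2_contingency(table.to_numpy(), correction=False)
    return Chi2Result(statistic=float(res.statistic), dof=int(res.dof),
                      p_value=float(res.pvalue), table=table)


def simulated_validation(n_replicates: int = 20, n_per_group: int = 20,
                         effect_delta: float = 0.3, base_fraction: float = 0.05,
                         depth_range: tuple = (1e3, 1e4), n_perm: int = 199,
                         seed: int = 0, grid=None) -> list[float]:
    """Replicate detection study on synthetic two-group cohorts.

    For each replicate: simulate a cohort with a between-group difference of
    ``effect_delta`` in the expanded-clone fraction and per-sample depths
    log-uniform over ``depth_range``; profile diversity over the default
    alpha grid; build the pairwise down-sampled distance matrix; and run the
    P-SVM LOOCV label-permutation test.  Returns the per-replicate p-values.
    """
    grid = grid or diversity.DEFAULT_GRID
    root = np.random.SeedSequence(seed)
    pvals = []
    for child in root.spawn(n_replicates):
        s1, s2, s3 = (int(x) for x in child.generate_state(3) % (2**31))
        cspec = simkit.two_group_cohort(
            n_per_group=n_per_group, effect_delta=effect_delta,
            base_fraction=base_fraction, depth_range=depth_range, seed=s1)
        samples = simkit.simulate_cohort(cspec)
        vecs = [s.repertoire.to_clonotype_vector() for s in samples]
        dm = diversity.distance_matrix(vecs, grid, seed=s2)
        labels = np.array([1 if s.group == "B" else -1 for s in samples])
        res = classify.permutation_test(dm.values, labels, n_perm=n_perm, seed=s3)
        pvals.append(res.p_value)
    return pvals


# --------------------------------------------------------------------------
# End-to-end run


@dataclass
class RunConfig:
    """Validated configuration for a full simulated-cohort analysis run."""

    seed: int = 0
    n_per_group: int = 20
    effect_delta: float = 0.3
    base_fraction: float = 0.05
    depth_range: tuple = (1e3, 1e4)
    chain: str = "beta"
    cell_type: str = "CD8"
    alpha_min: float = 0.0
    alpha_max: float = 10.0
    alpha_step: float = 0.2
    n_perm: int = 199
    mds_dims: int = 2
    psvm_C: float = 10.0
    psvm_epsilon: float = 0.05
    out_dir: str = "tcrdiv_run"

    def __post_init__(self) -> None:
        if self.chain not in simkit.CHAIN_TO_LOCUS:
            raise ValueError(f"unknown chain {self.chain!r}; "
                             f"choose from {sorted(simkit.CHAIN_TO_LOCUS)}")
        if self.n_perm < 1 or self.n_per_group < 2:
            raise ValueError("invalid permutation or group-size setting")
        self.grid = diversity.AlphaGrid(self.alpha_min, self.alpha_max, self.alpha_step)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "grid"}
        d["depth_range"] = list(self.depth_range)
        return d


def _stage_seed(master: int, stage: str) -> int:
    """Per-stage seed derived from the master seed and the stage name, so a
    stage re-run is stable under upstream edits."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_all(config: RunConfig) -> dict:
    """Simulate a two-group cohort and run diversity -> MDS -> classification.

    Writes distance matrix, profiles, MDS coordinates/eigenvalues/figure,
    classification report and a manifest under ``config.out_dir``; returns a
    summary dict.  Tables are byte-identical under a fixed config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("run_all: output directory %s", out)

    stage = "simulate"
    try:
        cspec = simkit.two_group_cohort(
            n_per_group=config.n_per_group, effect_delta=config.effect_delta,
            base_fraction=config.base_fraction, depth_range=config.depth_range,
            seed=_stage_seed(config.seed, "simulate"), chain=config.chain)
        samples = simkit.simulate_cohort(cspec)
        meta = simkit.cohort_metadata(samples)
        meta.to_csv(out / "metadata.csv", index=False)
        vectors = [s.repertoire.to_clonotype_vector() for s in samples]

        stage = "diversity"
        dm = diversity.distance_matrix(vectors, config.grid,
                                       seed=_stage_seed(config.seed, "diversity"))
        dm.to_tsv(out / "distance_matrix.tsv")
        diversity.profiles_frame(vectors, config.grid).to_csv(
            out / "profiles.tsv", sep="\t")

        stage = "mds"
        emb = embed.classical_mds(dm, k=config.mds_dims)
        emb.to_frame().to_csv(out / "mds_coordinates.tsv", sep="\t")
        pd.Series(emb.eigenvalues, name="eigenvalue").to_csv(
            out / "mds_eigenvalues.tsv", sep="\t", index_label="rank")
        embed.plot_embedding(emb, dict(zip(meta.sample_id, meta.group)),
                             out / "mds.png")

        stage = "classify"
        labels = np.where(meta.group.to_numpy() == "B", 1, -1)
        result = classify.permutation_test(
            dm.values, labels, C=config.psvm_C, epsilon=config.psvm_epsilon,
            n_perm=config.n_perm, seed=_stage_seed(config.seed, "classify"),
            comparison="A vs. B")
        report = pd.DataFrame([{
            "comparison": result.comparison,
            "cell_type": config.cell_type, "chain": config.chain,
            "observed_score": result.observed_score,
            "n_permutations": result.n_permutations,
            "p_value": result.p_value, "truncated": result.truncated,
        }])
        report.to_csv(out / "classification.tsv", sep="\t", index=False)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = {
        "config": config.to_dict(),
        "stages": ["simulate", "diversity", "mds", "classify"],
        "stage_seeds": {s: _stage_seed(config.seed, s)
                        for s in ("simulate", "diversity", "classify")},
        "n_samples": len(samples),
        "p_value": result.p_value,
        "observed_score": result.observed_score,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("run_all: p=%.4g score=%.3f", result.p_value, result.observed_score)
    return manifest
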