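"""Plate data model and the pharmacoscopy scoring engine.

Ex-vivo drug screens seed patient-derived mononuclear cells into 384-well
imaging plates.  Each well yields single-cell counts of viable cells that
stain positive or negative for one or more blast (lineage) markers.  The
central statistic is the relative blast fraction (RBF): the fraction of
marker-positive viable cells in a drug-treated well divided by the mean
marker-positive viable fraction across DMSO vehicle-control wells.

    RBF = 1   no on-target effect
    RBF < 1   on-target (blast-specific) kill
    RBF > 1   relative blast enrichment, i.e. ex-vivo chemoresistance

Per patient and marker, per-drug mean RBFs are normalised into
pharmacoscopy (PCY) scores via ``(1 - RBF) / max(1 - RBF)``: 1 marks the
strongest on-target response, 0 no effect, negative values resistance.
Summing the scores of an administered regimen over all measured markers
gives the integrated pharmacoscopy score (i-PCY) for one patient.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

logger = logging.getLogger(__name__)

CONTROL_DRUG = "DMSO"

#: columns required in a long-format well-count CSV
WELL_TABLE_COLUMNS = [
    "patient_id",
    "plate_id",
    "well",
    "drug",
    "concentration_um",
    "replicate",
    "marker",
    "n_viable_marker_pos",
    "n_viable_marker_neg",
    "n_total_cells",
]

_WELL_RE = re.compile(r"^([A-P])(\d{1,2})$")


class SchemaError(ValueError):
    """The input table does not have the expected columns."""


class ValidationError(ValueError):
    """A row violates a count or annotation invariant."""


class ControlMissingError(ValueError):
    """A patient has no DMSO control wells."""


def parse_well_coordinate(well: str) -> tuple[int, int]:
    """Parse a 384-well coordinate like ``'B07'`` into 0-based (row, column).

    Raises :class:`ValidationError` outside the 16x24 grid (rows A-P,
    columns 1-24).
    """
    m = _WELL_RE.match(str(well).strip().upper())
    if not m:
        raise ValidationError(f"malformed well coordinate {well!r}")
    row = ord(m.group(1)) - ord("A")
    col = int(m.group(2)) - 1
    if not (0 <= col < 24):
        raise ValidationError(f"well column out of 1..24 in {well!r}")
    return row, col


@dataclass
class WellRecord:
    """One well's annotations plus single-cell-derived viable counts.

    ``n_viable_marker_pos``/``_neg`` map marker name -> count, so a well
    stained for several markers is a single record.
    """

    patient_id: str
    plate_id: str
    well: str
    drug: str
    concentration_um: float
    replicate: int
    n_viable_marker_pos: dict[str, int] = field(default_factory=dict)
    n_viable_marker_neg: dict[str, int] = field(default_factory=dict)
    n_total_cells: int = 0

    def __post_init__(self) -> None:
        parse_well_coordinate(self.well)
        if self.concentration_um < 0:
            raise ValidationError(
                f"negative concentration in well {self.well}: {self.concentration_um}"
            )
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")
        if self.n_total_cells < 0:
            raise ValidationError("n_total_cells must be >= 0")
        for marker in self.n_viable_marker_pos:
            pos = self.n_viable_marker_pos[marker]
            neg = self.n_viable_marker_neg.get(marker, 0)
            if pos < 0 or neg < 0:
                raise ValidationError(f"negative count for marker {marker}")
            if pos + neg > self.n_total_cells:
                raise ValidationError(
                    f"viable count {pos + neg} exceeds n_total_cells "
                    f"{self.n_total_cells} for marker {marker} in well {self.well}"
                )
        if self.is_control and self.concentration_um != 0:
            raise ValidationError("control (DMSO) wells must have concentration 0")

    @property
    def is_control(self) -> bool:
        return self.drug == CONTROL_DRUG

    def viable_fraction(self, marker: str) -> float | None:
        """Fraction of viable cells positive for *marker*; None if no viable cells."""
        pos = self.n_viable_marker_pos[marker]
        neg = self.n_viable_marker_neg[marker]
        if pos + neg == 0:
            return None
        return pos / (pos + neg)


@dataclass
class IPcyResult:
    """Integrated pharmacoscopy score for one patient's regimen."""

    patient_id: str
    administered_drugs: list[str]
    markers: list[str]
    i_pcy: float
    component_scores: pd.DataFrame  # index drug, columns marker


# ---------------------------------------------------------------------------
# I/O


def read_well_table(path) -> list[WellRecord]:
    """Read a long-format well-count CSV into validated :class:`WellRecord`\\ s.

    One CSV row per well x marker; rows for the same well are merged into a
    single record.  Duplicate (patient, plate, well, marker) rows, negative
    counts and patients without DMSO control wells are rejected.
    """
    df = pd.read_csv(path)
    missing = [c for c in WELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")

    for col in ("n_viable_marker_pos", "n_viable_marker_neg", "n_total_cells"):
        bad = df.index[df[col] < 0]
        if len(bad):
            raise ValidationError(f"negative {col} at row {int(bad[0]) + 2} of {path}")

    key_cols = ["patient_id", "plate_id", "well", "marker"]
    dup = df.duplicated(subset=key_cols)
    if dup.any():
        row = df.loc[dup.idxmax(), key_cols].tolist()
        raise ValidationError(f"duplicate well/marker row: {row}")

    records: dict[tuple, WellRecord] = {}
    for _, row in df.iterrows():
        key = (row["patient_id"], row["plate_id"], row["well"])
        rec = records.get(key)
        if rec is None:
            rec = WellRecord(
                patient_id=str(row["patient_id"]),
                plate_id=str(row["plate_id"]),
                well=str(row["well"]),
                drug=str(row["drug"]),
                concentration_um=float(row["concentration_um"]),
                replicate=int(row["replicate"]),
                n_total_cells=int(row["n_total_cells"]),
            )
            records[key] = rec
        rec.n_viable_marker_pos[str(row["marker"])] = int(row["n_viable_marker_pos"])
        rec.n_viable_marker_neg[str(row["marker"])] = int(row["n_viable_marker_neg"])
    out = []
    for rec in records.values():
        # re-validate with marker maps populated
        rec.__post_init__()
        out.append(rec)

    for patient in {r.patient_id for r in out}:
        if not any(r.is_control for r in out if r.patient_id == patient):
            raise ControlMissingError(f"no DMSO control wells for patient {patient}")
    return out


def wells_to_frame(wells: list[WellRecord]) -> pd.DataFrame:
    """Flatten records back to the long (one row per well x marker) layout."""
    rows = []
    for w in wells:
        for marker in w.n_viable_marker_pos:
            rows.append(
                {
                    "patient_id": w.patient_id,
                    "plate_id": w.plate_id,
                    "well": w.well,
                    "drug": w.drug,
                    "concentration_um": w.concentration_um,
                    "replicate": w.replicate,
                    "marker": marker,
                    "n_viable_marker_pos": w.n_viable_marker_pos[marker],
                    "n_viable_marker_neg": w.n_viable_marker_neg[marker],
                    "n_total_cells": w.n_total_cells,
                }
            )
    return pd.DataFrame(rows)


def write_well_table(wells: list[WellRecord], path) -> None:
    wells_to_frame(wells).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# RBF


@dataclass
class RbfResult:
    """Per-well, per-concentration and mean RBF for one drug."""

    drug: str
    marker: str
    rbf_per_well: list[float]
    rbf_per_concentration: dict[float, float]
    rbf_mean: float  # NaN when every drug well was excluded
    n_excluded: int = 0


def control_fractions(
    wells: list[WellRecord], marker: str
) -> tuple[list[float], float]:
    """Per-DMSO-well marker-positive viable fractions and their mean."""
    fracs = []
    for w in wells:
        if w.is_control:
            f = w.viable_fraction(marker)
            if f is not None:
                fracs.append(f)
    if not fracs:
        raise ControlMissingError(
            f"no usable DMSO control wells for marker {marker!r}"
        )
    return fracs, float(np.mean(fracs))


def compute_rbf(wells: list[WellRecord], drug: str, marker: str) -> RbfResult:
    """RBF of *drug* for one patient x marker.

    Each drug well's marker-positive viable fraction is divided by the mean
    control-well fraction.  Wells with zero viable cells are excluded with a
    warning.  The mean RBF averages replicates within each concentration
    first, then concentrations (unweighted); raw values are never capped
    (capping at 1.2 is a display convention only).
    """
    _, ctrl_mean = control_fractions(wells, marker)
    per_well: list[float] = []
    by_conc: dict[float, list[float]] = {}
    n_excluded = 0
    for w in wells:
        if w.drug != drug:
            continue
        f = w.viable_fraction(marker)
        if f is None:
            n_excluded += 1
            logger.warning(
                "well %s (%s, %g uM): zero viable cells, excluded from RBF",
                w.well, drug, w.concentration_um,
            )
            continue
        rbf = f / ctrl_mean
        per_well.append(rbf)
        by_conc.setdefault(w.concentration_um, []).append(rbf)
    if not per_well and n_excluded == 0:
        raise ValueError(f"no wells for drug {drug!r}")
    per_conc = {c: float(np.mean(v)) for c, v in sorted(by_conc.items())}
    mean = float(np.mean(list(per_conc.values()))) if per_conc else float("nan")
    return RbfResult(drug, marker, per_well, per_conc, mean, n_excluded)


def control_rbfs(wells: list[WellRecord], marker: str) -> list[float]:
    """Per-control-well RBFs (each control fraction over the control mean).

    Their mean is 1 by construction; they serve as the reference sample for
    per-drug significance testing.
    """
    fracs, ctrl_mean = control_fractions(wells, marker)
    return [f / ctrl_mean for f in fracs]


def drug_significance(
    rbf_per_replicate: list[float],
    control_rbfs_: list[float],
    alpha: float = 0.05,
) -> tuple[float, bool]:
    """Two-tailed Welch t-test of drug-well RBFs against control-well RBFs.

    Returns ``(p_value, significant)``; with fewer than two values on
    either side the p-value is NaN and the flag False.
    """
    a = np.asarray(rbf_per_replicate, dtype=float)
    b = np.asarray(control_rbfs_, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return float("nan"), False
    if np.allclose(a, a[0]) and np.allclose(b, b[0]) and math.isclose(a[0], b[0]):
        return 1.0, False  # identical constant samples: t = 0
    p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    if math.isnan(p):
        return float("nan"), False
    return p, bool(p < alpha)


# ---------------------------------------------------------------------------
# Pharmacoscopy scores

DEGENERATE_EPS = 1e-9


def pcy_scores(rbf_means: dict[str, float]) -> dict[str, float]:
    """Normalise per-drug mean RBFs into pharmacoscopy scores.

    score_d = (1 - RBF_d) / max_d(1 - RBF_d), the max taken over drugs
    within one patient x marker.  When no drug beats control
    (max(1 - RBF) <= 0) the formula is undefined; all scores are set to 0
    ("no ex-vivo effect") and a warning is logged.
    """
    if not rbf_means:
        raise ValueError("need at least one drug")
    one_minus = {d: 1.0 - r for d, r in rbf_means.items()}
    denom = max(one_minus.values())
    if denom <= DEGENERATE_EPS:
        logger.warning(
            "max(1 - RBF) = %.3g <= 0: no drug beats control, all scores set to 0",
            denom,
        )
        return {d: 0.0 for d in rbf_means}
    return {d: v / denom for d, v in one_minus.items()}


def rank_drugs(rows: pd.DataFrame) -> pd.DataFrame:
    """Rank a per-drug response table by ascending mean RBF.

    Expects a ``drug`` and an ``rbf_mean`` column; ties broken
    lexicographically by drug name.  Adds/overwrites a 1-based ``rank``
    column and returns the table sorted.
    """
    out = rows.sort_values(["rbf_mean", "drug"], kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def build_drug_response_table(
    wells: list[WellRecord], alpha: float = 0.05, bh_correct: bool = False
) -> pd.DataFrame:
    """Full per patient x marker x drug response table.

    Computes mean RBF, Welch-test p-value against controls, significance
    flag, rank and pharmacoscopy score for every drug; one row per
    patient x marker x drug.  With ``bh_correct`` p-values are
    Benjamini-Hochberg adjusted within each patient x marker before
    flagging significance.
    """
    frames = []
    by_patient: dict[str, list[WellRecord]] = {}
    for w in wells:
        by_patient.setdefault(w.patient_id, []).append(w)
    for patient, pw in sorted(by_patient.items()):
        markers = sorted({m for w in pw for m in w.n_viable_marker_pos})
        drugs = sorted({w.drug for w in pw if not w.is_control})
        for marker in markers:
            ctrl = control_rbfs(pw, marker)
            recs = []
            for drug in drugs:
                res = compute_rbf(pw, drug, marker)
                p, sig = drug_significance(res.rbf_per_well, ctrl, alpha=alpha)
                recs.append(
                    {
                        "patient_id": patient,
                        "marker": marker,
                        "drug": drug,
                        "rbf_mean": res.rbf_mean,
                        "rbf_per_replicate": res.rbf_per_well,
                        "p_value": p,
                        "significant": sig,
                    }
                )
            tab = pd.DataFrame(recs).dropna(subset=["rbf_mean"])
            if bh_correct:
                tab = _bh_adjust(tab, alpha)
            tab = rank_drugs(tab)
            scores = pcy_scores(dict(zip(tab["drug"], tab["rbf_mean"])))
            tab["pcy_score"] = tab["drug"].map(scores)
            frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def _bh_adjust(tab: pd.DataFrame, alpha: float) -> pd.DataFrame:
    from statsmodels.stats.multitest import multipletests

    ok = tab["p_value"].notna()
    tab = tab.copy()
    if ok.any():
        rej, p_adj, _, _ = multipletests(tab.loc[ok, "p_value"], alpha=alpha, method="fdr_bh")
        tab.loc[ok, "p_value"] = p_adj
        tab.loc[ok, "significant"] = rej
    return tab


# ---------------------------------------------------------------------------
# i-PCY and resistance summaries


def integrate_ipcy(
    component_scores: pd.DataFrame,
    administered: list[str],
    patient_id: str = "",
) -> IPcyResult:
    """Sum pharmacoscopy scores over a regimen's drugs and all markers.

    ``component_scores`` is a drug x marker table of pcy scores.  Every
    administered drug must be present for every marker; missing
    combinations raise with the full list.
    """
    missing = [
        (d, m)
        for d in administered
        for m in component_scores.columns
        if d not in component_scores.index or pd.isna(component_scores.loc[d, m])
    ]
    if missing:
        raise KeyError(f"missing drug/marker scores: {missing}")
    sub = component_scores.loc[list(administered)]
    return IPcyResult(
        patient_id=patient_id,
        administered_drugs=list(administered),
        markers=list(component_scores.columns),
        i_pcy=float(sub.to_numpy().sum()),
        component_scores=sub,
    )


def chemoresistance_fraction(
    scores: dict[str, float], threshold: float = -0.1
) -> float:
    """Fraction of tested drugs with pharmacoscopy score below *threshold*.

    The default -0.1 defines ex-vivo chemoresistance; alternates (-0.2,
    -0.3, -0.4) behave the same way.
    """
    if not scores:
        raise ValueError("no drug scores")
    vals = np.fromiter(scores.values(), dtype=float)
    return float(np.mean(vals < threshold))


# ---------------------------------------------------------------------------
# Clustering of drug-response profiles


def _masked_correlation_distance(mat: np.ndarray) -> np.ndarray:
    """Condensed (1 - Pearson r) distance with pairwise NaN masking."""
    n = mat.shape[0]
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(np.isnan(mat[i]) | np.isnan(mat[j]))
            if ok.sum() < 2:
                out.append(1.0)
                continue
            a, b = mat[i, ok], mat[j, ok]
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                d = 0.0 if np.allclose(a, b) else 1.0
            else:
                d = 1.0 - float(np.corrcoef(a, b)[0, 1])
            out.append(max(d, 0.0))
    return np.asarray(out)


@dataclass
class ClusterResult:
    linkage: np.ndarray | None
    leaf_order: list


def cluster_profiles(score_table: pd.DataFrame, axis: str = "columns") -> ClusterResult:
    """Average-linkage hierarchical clustering of a score matrix.

    Distance is 1 - Pearson correlation with missing values masked
    pairwise.  ``axis='columns'`` clusters drugs, ``axis='rows'`` clusters
    patient x marker profiles.  Leaf order is deterministic (scipy's
    ordering on a fixed input).  A single item yields a trivial tree.
    """
    mat = score_table.to_numpy(dtype=float)
    labels = list(score_table.columns) if axis == "columns" else list(score_table.index)
    if axis == "columns":
        mat = mat.T
    if mat.shape[0] < 2:
        return ClusterResult(linkage=None, leaf_order=labels)
    dist = _masked_correlation_distance(mat)
    Z = hierarchy.linkage(dist, method="average")
    order = hierarchy.leaves_list(Z)
    return ClusterResult(linkage=Z, leaf_order=[labels[i] for i in order])
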