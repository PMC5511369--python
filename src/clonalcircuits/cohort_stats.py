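"""Contingency tables, connectivity-rate comparisons and cohort analyses.

Rates are reported as percentages rounded half-up to one decimal, the
convention of the source counts.  Group comparisons use the Pearson
chi-square test without continuity correction by default (Fisher's exact
test is available for 2x2 tables); no multiple-testing correction is
applied.

The bundled ``paper_counts.csv`` fixture transcribes every (k, n) connection
count reported in the source study's results, and ``paper_comparisons.csv``
lists the group contrasts with the significance labels given there;
``reproduce_paper_report`` recomputes both and marks each PASS/FAIL.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact

from .errors import DegenerateTableError, ValidationError

LINEAGE_CLASSES = ("sparse_cluster", "non_lineage", "dense_dense")
SUBTYPE_PAIRS = ("FS_FS", "nonFS_nonFS", "FS_nonFS")
CHEMICAL_STATES = ("none", "uni", "bi")

DEFAULT_DISTANCE_BINS_UM = (0.0, 20.0, 50.0, 100.0, 150.0, 200.0, np.inf)
DEFAULT_AGE_BINS_P = (0, 7, 11, 14, 22, np.inf)


@dataclass(frozen=True)
class PairRecord:
    """One recorded pair with its grouping variables and outcomes."""

    pair_id: int
    lineage_class: str
    subtype_pair: str
    intersoma_dist_um: float
    age_P: int
    layer: str
    area: str
    electrical: bool
    chemical: str  # none | uni | bi
    both_output_to_common_PN: Optional[bool] = None

    def __post_init__(self):
        if self.lineage_class not in LINEAGE_CLASSES:
            raise ValidationError(f"unknown lineage class: {self.lineage_class!r}")
        if self.subtype_pair not in SUBTYPE_PAIRS:
            raise ValidationError(f"unknown subtype pair: {self.subtype_pair!r}")
        if self.chemical not in CHEMICAL_STATES:
            raise ValidationError(f"unknown chemical state: {self.chemical!r}")
        if self.intersoma_dist_um < 0:
            raise ValidationError("intersoma distance must be >= 0")


def records_frame(records: Sequence[PairRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_frame(list(records))


# ---------------------------------------------------------------------------
# Rates and comparisons
# ---------------------------------------------------------------------------


def rate(k: int, n: int) -> float:
    """Percentage 100*k/n rounded half-up to one decimal."""
    if n <= 0:
        raise ValidationError("rate undefined for n = 0")
    if not 0 <= k <= n:
        raise ValidationError("need 0 <= k <= n")
    return float(
        (Decimal(100) * Decimal(k) / Decimal(n)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


@dataclass
class RateComparison:
    groups: list  # (label, k, n, rate_percent)
    test: str     # 'chi2' | 'fisher' | 'none'
    statistic: float
    p_value: float
    meta: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def significance_label(p: float) -> str:
    if p < 0.001:
        return "p<0.001"
    if p < 0.01:
        return "p<0.01"
    if p < 0.05:
        return "p<0.05"
    return "NS"


def compare_rates(groups, method: str = "chi2", labels=None) -> RateComparison:
    """Compare success rates across >= 2 groups given as (k, n) pairs.

    ``method='chi2'``: Pearson chi-square on the 2xk table, no continuity
    correction.  ``method='fisher'``: Fisher's exact test (2 groups only).
    """
    groups = [(int(k), int(n)) for k, n in groups]
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups to compare")
    if any(n <= 0 or not 0 <= k <= n for k, n in groups):
        raise ValidationError("each group needs n > 0 and 0 <= k <= n")
    table = np.array([[k, n - k] for k, n in groups])
    if (table.sum(axis=0) == 0).any():
        raise DegenerateTableError(
            "all-success or all-failure margin: the test is undefined"
        )
    if labels is None:
        labels = [f"group_{i}" for i in range(len(groups))]
    out_groups = [(lab, k, n, rate(k, n)) for lab, (k, n) in zip(labels, groups)]
    if method == "fisher":
        if len(groups) != 2:
            raise ValidationError("Fisher's exact test requires exactly 2 groups")
        stat, p = fisher_exact(table)
        return RateComparison(out_groups, "fisher", float(stat), float(p))
    if method != "chi2":
        raise ValidationError("method must be 'chi2' or 'fisher'")
    stat, p, _dof, expected = chi2_contingency(table, correction=False)
    return RateComparison(
        out_groups,
        "chi2",
        float(stat),
        float(p),
        meta={"min_expected_cell": float(expected.min())},
    )


# ---------------------------------------------------------------------------
# Stratified cohort analyses
# ---------------------------------------------------------------------------


def _outcome_series(df: pd.DataFrame, outcome: str) -> pd.Series:
    if outcome == "electrical":
        return df["electrical"].astype(bool)
    if outcome == "chemical":
        return df["chemical"].isin(("uni", "bi"))
    raise ValidationError("outcome must be 'electrical' or 'chemical'")


def _strata(df: pd.DataFrame, stratifier: str, distance_bins, age_bins) -> pd.Series:
    if stratifier == "lineage":
        return df["lineage_class"].astype(str)
    if stratifier == "subtype":
        return df["subtype_pair"].astype(str)
    if stratifier == "layer":
        return df["layer"].astype(str)
    if stratifier == "distance_bins":
        return pd.cut(
            df["intersoma_dist_um"], bins=list(distance_bins), right=False
        ).astype(str)
    if stratifier == "age_bins":
        return pd.cut(df["age_P"], bins=list(age_bins), right=False).astype(str)
    raise ValidationError(f"unknown stratifier: {stratifier!r}")


def stratified_rates(
    records,
    stratifier: str,
    outcome: str = "electrical",
    distance_bins=DEFAULT_DISTANCE_BINS_UM,
    age_bins=DEFAULT_AGE_BINS_P,
) -> pd.DataFrame:
    """Per-stratum (k, n, rate) for each lineage class, with a chi-square
    contrast across lineage classes within each stratum.

    Strata with fewer than 2 non-empty lineage classes carry a NaN p-value
    (no test).  When the stratifier is ``'lineage'`` itself, the test is a
    single contrast across the classes.
    """
    df = _as_frame(records)
    if df.empty:
        raise ValidationError("empty cohort")
    success = _outcome_series(df, outcome)
    strata = _strata(df, stratifier, distance_bins, age_bins)
    rows = []
    if stratifier == "lineage":
        groups = []
        for cls in [c for c in LINEAGE_CLASSES if (strata == c).any()]:
            m = strata == cls
            groups.append((cls, int(success[m].sum()), int(m.sum())))
        p = stat = np.nan
        if len(groups) >= 2:
            cmp_res = compare_rates([(k, n) for _, k, n in groups])
            p, stat = cmp_res.p_value, cmp_res.statistic
        for cls, k, n in groups:
            rows.append(
                {
                    "stratum": "all",
                    "lineage_class": cls,
                    "k": k,
                    "n": n,
                    "rate_percent": rate(k, n),
                    "chi2": stat,
                    "p_value": p,
                }
            )
        return pd.DataFrame(rows)
    for stratum in strata.unique():
        sm = strata == stratum
        groups = []
        for cls in LINEAGE_CLASSES:
            m = sm & (df["lineage_class"] == cls)
            n = int(m.sum())
            k = int(success[m].sum())
            if n > 0:
                groups.append((cls, k, n))
            else:
                rows.append(
                    {
                        "stratum": stratum,
                        "lineage_class": cls,
                        "k": 0,
                        "n": 0,
                        "rate_percent": np.nan,
                        "chi2": np.nan,
                        "p_value": np.nan,
                    }
                )
        p = stat = np.nan
        if len(groups) >= 2:
            try:
                cmp_res = compare_rates([(k, n) for _, k, n in groups])
                p, stat = cmp_res.p_value, cmp_res.statistic
            except DegenerateTableError:
                pass
        for cls, k, n in groups:
            rows.append(
                {
                    "stratum": stratum,
                    "lineage_class": cls,
                    "k": k,
                    "n": n,
                    "rate_percent": rate(k, n),
                    "chi2": stat,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


def electrical_chemical_independence(records) -> dict[str, RateComparison]:
    """Cross-modality association tests on a pair cohort.

    Returns three comparisons: electrical coupling rate split by chemical
    status, chemical connection rate split by electrical status, and the
    bidirectional fraction of chemical connections split by electrical
    status.
    """
    df = _as_frame(records)
    elec = df["electrical"].astype(bool)
    chem = df["chemical"].isin(("uni", "bi"))
    out = {}
    out["electrical_by_chemical"] = compare_rates(
        [
            (int(elec[chem].sum()), int(chem.sum())),
            (int(elec[~chem].sum()), int((~chem).sum())),
        ],
        labels=["chem_connected", "chem_unconnected"],
    )
    out["chemical_by_electrical"] = compare_rates(
        [
            (int(chem[elec].sum()), int(elec.sum())),
            (int(chem[~elec].sum()), int((~elec).sum())),
        ],
        labels=["coupled", "uncoupled"],
    )
    bi = df["chemical"] == "bi"
    bi_groups = [
        ("coupled", int(bi[elec & chem].sum()), int((elec & chem).sum())),
        ("uncoupled", int(bi[~elec & chem].sum()), int((~elec & chem).sum())),
    ]
    try:
        out["bidirectional_by_electrical"] = compare_rates(
            [(k, n) for _, k, n in bi_groups], labels=["coupled", "uncoupled"]
        )
    except (ValidationError, DegenerateTableError):
        # an empty or degenerate group leaves the contrast undefined
        out["bidirectional_by_electrical"] = RateComparison(
            [(lab, k, n, rate(k, n) if n else float("nan")) for lab, k, n in bi_groups],
            "none",
            float("nan"),
            float("nan"),
        )
    return out


# ---------------------------------------------------------------------------
# Coordinated inhibitory output
# ---------------------------------------------------------------------------


def pair_records_from_connections(
    sessions: Sequence[tuple],
) -> tuple[pd.DataFrame, int]:
    """Assemble PairRecord rows from quadruple-session connection calls.

    Each session is ``(meta, interneuron_ids, pn_ids, results)`` where
    ``meta`` is a dict with the PairRecord grouping fields for the
    interneuron pair and ``results`` is the list of ConnectionResult objects
    from ``connectivity_detect.connection_matrix``.  The pair is coordinated
    iff both interneurons are chemically presynaptic to at least one common
    pyramidal cell.  Sessions without a pyramidal cell are excluded; the
    count of exclusions is returned alongside the frame.
    """
    rows, excluded = [], 0
    for pid, (meta, in_ids, pn_ids, results) in enumerate(sessions):
        if len(in_ids) != 2:
            raise ValidationError("each session needs exactly 2 interneurons")
        if not pn_ids:
            excluded += 1
            continue
        chem_edges = {
            d
            for r in results
            for d, c in r.chemical_by_direction.items()
            if c.connected
        }
        i, j = in_ids
        elec = any(
            r.electrical_coupled for r in results if r.pair == (min(i, j), max(i, j))
        )
        coordinated = any(
            (i, p) in chem_edges and (j, p) in chem_edges for p in pn_ids
        )
        if (i, j) in chem_edges and (j, i) in chem_edges:
            chem = "bi"
        elif (i, j) in chem_edges or (j, i) in chem_edges:
            chem = "uni"
        else:
            chem = "none"
        rows.append(
            {
                "pair_id": pid,
                "lineage_class": meta.get("lineage_class", "sparse_cluster"),
                "subtype_pair": meta.get("subtype_pair", "nonFS_nonFS"),
                "intersoma_dist_um": meta.get("intersoma_dist_um", 0.0),
                "age_P": meta.get("age_P", 14),
                "layer": meta.get("layer", "L2_3"),
                "area": meta.get("area", "SCX"),
                "electrical": bool(elec),
                "chemical": chem,
                "both_output_to_common_PN": bool(coordinated),
            }
        )
    return pd.DataFrame(rows), excluded


def coordinated_output(records) -> pd.DataFrame:
    """Coordinated-output rates stratified by lineage class and coupling.

    A pair counts as coordinated iff both interneurons are chemically
    presynaptic to at least one common pyramidal neuron
    (``both_output_to_common_PN``).  Records without a PN-target call are
    excluded.  Within each lineage class, coupled and non-coupled pairs are
    contrasted by chi-square.
    """
    df = _as_frame(records)
    df = df[df["both_output_to_common_PN"].notna()]
    if df.empty:
        raise ValidationError("no records carry a common-PN output call")
    coord = df["both_output_to_common_PN"].astype(bool)
    elec = df["electrical"].astype(bool)
    rows = []
    for cls in LINEAGE_CLASSES:
        m = df["lineage_class"] == cls
        if not m.any():
            continue
        groups = []
        for label, em in (("coupled", elec), ("uncoupled", ~elec)):
            n = int((m & em).sum())
            k = int(coord[m & em].sum())
            groups.append((label, k, n))
        p = stat = np.nan
        usable = [(k, n) for _, k, n in groups if n > 0]
        if len(usable) == 2:
            try:
                cmp_res = compare_rates(usable)
                p, stat = cmp_res.p_value, cmp_res.statistic
            except DegenerateTableError:
                pass
        for label, k, n in groups:
            rows.append(
                {
                    "lineage_class": cls,
                    "coupling": label,
                    "k": k,
                    "n": n,
                    "rate_percent": rate(k, n) if n else np.nan,
                    "chi2": stat,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bundled source-count fixture
# ---------------------------------------------------------------------------


def _data_path(name: str):
    return resources.files("clonalcircuits").joinpath("data").joinpath(name)


def load_paper_counts() -> pd.DataFrame:
    """Transcribed (analysis, group, k, n, printed percentage) counts."""
    with resources.as_file(_data_path("paper_counts.csv")) as p:
        return pd.read_csv(p)


def load_paper_comparisons() -> pd.DataFrame:
    """Transcribed group contrasts with their published significance labels."""
    with resources.as_file(_data_path("paper_comparisons.csv")) as p:
        return pd.read_csv(p)


def reproduce_paper_report() -> pd.DataFrame:
    """Recompute every transcribed rate and significance call; PASS/FAIL each.

    Rate rows pass when ``rate(k, n)`` equals the printed percentage to one
    decimal; comparison rows pass when the chi-square significance label
    matches the published one.
    """
    counts = load_paper_counts()
    comps = load_paper_comparisons()
    key = counts.set_index(["analysis", "group"])
    rows = []
    for _, r in counts.iterrows():
        computed = rate(int(r["k"]), int(r["n"]))
        printed = r["printed_pct"]
        if pd.isna(printed):
            status, printed_val = "NOT_PRINTED", np.nan
        else:
            printed_val = float(printed)
            status = "PASS" if abs(computed - printed_val) < 0.05 else "FAIL"
        rows.append(
            {
                "kind": "rate",
                "id": f"{r['analysis']}:{r['group']}",
                "computed": computed,
                "expected": printed_val,
                "status": status,
            }
        )
    for _, c in comps.iterrows():
        ga = key.loc[(c["analysis"], c["group_a"])]
        gb = key.loc[(c["analysis"], c["group_b"])]
        res = compare_rates(
            [(int(ga["k"]), int(ga["n"])), (int(gb["k"]), int(gb["n"]))],
            labels=[c["group_a"], c["group_b"]],
        )
        label = significance_label(res.p_value)
        expected = str(c["expected_label"])
        ok = label == expected if expected != "NS" else res.p_value >= 0.05
        rows.append(
            {
                "kind": "comparison",
                "id": c["comparison_id"],
                "computed": res.p_value,
                "expected": expected,
                "status": "PASS" if ok else "FAIL",
            }
        )
    return pd.DataFrame(rows)
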