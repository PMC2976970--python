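"""Dual-normalization scoring of a plate-based reporter screen.

The analysis follows the screen's design: duplicate luminescence readings
per condition are averaged; the Notch-induced reporter signal (NΔecn >
m3-luc) is normalized two ways, by the constitutive control promoter
(con-luc, method ``BY_CON``) and by the uninduced reporter (m3-luc, method
``BY_M3``); log2 ratios are standardized within the 96-well stock-plate
group each dsRNA came from; and hits are the ratios whose stock-plate
z-score crosses a fixed cutoff (|z| > 2 for BY_CON, |z| > 1.8 for BY_M3).

Three quality filters run before z-scoring so removed wells never
contaminate the group statistics:

* off-target filter — dsRNAs with more than one predicted off-target are
  removed outright; single-off-target dsRNAs are kept but flagged;
* viability filter — wells whose con-luc signal sits in the low tail
  (z < −2 of the genome-wide log2 con-luc distribution) indicate dead or
  transcriptionally crippled cells and are removed;
* replicate-error filter — ratios whose duplicate measurements disagree
  (error z > 3 in the genome-wide distribution of |log2 r1 − log2 r2|)
  are removed.

``ScreenModel`` wraps the pipeline in a fit/results interface; the stage
functions below are usable on their own.
"""

from __future__ import annotations

from dataclasses import dataclass
import io as _io

import numpy as np
import pandas as pd

#: normalization methods: induced reporter over control promoter / over
#: uninduced reporter
METHODS = ("BY_CON", "BY_M3")
_DENOMINATOR = {"BY_CON": "CON_LUC", "BY_M3": "M3_LUC"}

FLAG_COLUMNS = (
    "offtarget_single",
    "removed_offtarget",
    "removed_viability",
    "removed_error",
    "nonpositive",
    "incomplete",
)


@dataclass(frozen=True)
class ThresholdConfig:
    """Cutoffs of the screen analysis.

    z_cut_con / z_cut_m3 are the |z| hit cutoffs for the two normalization
    methods (the uninduced-reporter distribution has heavier-tailed
    outliers, so its cutoff is set lower to make the two methods select
    comparable tails). error_z_max bounds replicate discordance,
    viability_z_min floors the control-promoter signal, and dsRNAs with
    more than max_offtargets predicted off-targets are discarded.
    """

    z_cut_con: float = 2.0
    z_cut_m3: float = 1.8
    error_z_max: float = 3.0
    viability_z_min: float = -2.0
    max_offtargets: int = 1

    def __post_init__(self):
        for name in ("z_cut_con", "z_cut_m3"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0")
        for name in ("error_z_max", "viability_z_min"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def z_cut(self, method: str) -> float:
        return self.z_cut_con if method == "BY_CON" else self.z_cut_m3


def average_replicates(measurements: pd.DataFrame, plate_map: pd.DataFrame) -> pd.DataFrame:
    """Average plate-copy replicates per (dsRNA, assay).

    Returns one row per (dsrna_id, assay) with the arithmetic mean, the
    per-copy signals in columns ``copy_<k>``, and an ``incomplete`` flag
    for wells missing any replicate (mean of the observed copies; nothing
    is imputed). Raises on measurement wells absent from the plate map.
    """
    merged = measurements.merge(
        plate_map[["screen_plate_id", "well", "dsrna_id", "stock_plate_id"]],
        on=["screen_plate_id", "well"],
        how="left",
    )
    unmapped = merged["dsrna_id"].isna()
    if unmapped.any():
        bad = merged.loc[unmapped, ["screen_plate_id", "well"]].drop_duplicates()
        raise ValueError(
            "measurement wells missing from the plate map: "
            + ", ".join(f"{p}:{w}" for p, w in bad.itertuples(index=False))
        )
    n_reps = int(merged["plate_copy"].max())
    wide = merged.pivot_table(
        index=["dsrna_id", "stock_plate_id", "assay"],
        columns="plate_copy",
        values="signal",
        aggfunc="first",
    )
    wide = wide.reindex(columns=range(1, n_reps + 1))
    out = wide.rename(columns=lambda k: f"copy_{k}").reset_index()
    copy_cols = [f"copy_{k}" for k in range(1, n_reps + 1)]
    out["mean_signal"] = out[copy_cols].mean(axis=1)
    out["n_obs"] = out[copy_cols].notna().sum(axis=1)
    out["incomplete"] = out["n_obs"] < n_reps
    return out


def offtarget_filter(annotations: pd.DataFrame, max_offtargets: int = 1):
    """Apply the predicted-off-target rule.

    Returns ``(removed, flagged_single)`` sets of dsrna_ids: counts above
    the threshold are removed; dsRNAs with exactly one predicted
    off-target are kept but carry a flag through every output.
    """
    counts = annotations.set_index("dsrna_id")["offtarget_count"]
    removed = set(counts.index[counts > max_offtargets])
    flagged = set(counts.index[counts == 1]) - removed
    return removed, flagged


def viability_filter(con_means: pd.Series, viability_z_min: float = -2.0) -> set:
    """Remove wells whose control-promoter signal is in the low tail.

    ``con_means`` maps dsrna_id -> averaged con-luc signal. The z-score is
    computed on log2 signals over the genome-wide distribution; only the
    low side is removed (bright wells are never a viability problem).
    """
    vals = con_means[con_means > 0]
    if len(vals) < 3:
        raise ValueError("viability filter needs at least 3 positive con-luc values")
    logs = np.log2(vals.astype(float))
    sd = logs.std(ddof=1)
    if sd <= 1e-12 * max(1.0, abs(logs.mean())):
        raise ValueError("degenerate con-luc distribution (zero spread)")
    z = (logs - logs.mean()) / sd
    return set(z.index[z < viability_z_min]) | set(con_means.index[~(con_means > 0)])


def compute_ratios(signals: pd.DataFrame, method: str) -> pd.DataFrame:
    """Log2 ratio and replicate error for one normalization method.

    ``signals`` is the output of :func:`average_replicates`. The ratio is
    log2(mean NΔecn>m3-luc / mean denominator); the replicate error is the
    spread of the per-copy log2 ratios (|log2 r1 − log2 r2| for
    duplicates). Wells with a non-positive averaged numerator or
    denominator get a NaN ratio and the ``nonpositive`` flag; wells with
    fewer than two complete replicate pairs get NaN replicate error and
    ``incomplete``.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; use one of {METHODS}")
    copy_cols = [c for c in signals.columns if c.startswith("copy_")]
    num = signals[signals["assay"] == "NDELTA_M3"].set_index("dsrna_id")
    den = signals[signals["assay"] == _DENOMINATOR[method]].set_index("dsrna_id")
    common = num.index.intersection(den.index)
    num, den = num.loc[common], den.loc[common]

    nonpositive = ~((num["mean_signal"] > 0) & (den["mean_signal"] > 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_ratio = np.where(
            nonpositive, np.nan, np.log2(num["mean_signal"] / den["mean_signal"])
        )
        copy_log2 = np.full((len(common), len(copy_cols)), np.nan)
        for j, c in enumerate(copy_cols):
            n_c, d_c = num[c].to_numpy(float), den[c].to_numpy(float)
            ok = (n_c > 0) & (d_c > 0)
            copy_log2[ok, j] = np.log2(n_c[ok] / d_c[ok])
    n_pairs = np.sum(~np.isnan(copy_log2), axis=1)
    replicate_error = np.full(len(common), np.nan)
    enough = n_pairs >= 2
    if enough.any():
        replicate_error[enough] = (
            np.nanmax(copy_log2[enough], axis=1) - np.nanmin(copy_log2[enough], axis=1)
        )
    return pd.DataFrame(
        {
            "dsrna_id": common,
            "stock_plate_id": num["stock_plate_id"].to_numpy(),
            "method": method,
            "log2_ratio": log2_ratio,
            "replicate_error": replicate_error,
            "nonpositive": nonpositive.to_numpy(),
            "incomplete": n_pairs < len(copy_cols),
        }
    )


def error_filter(ratios: pd.DataFrame, error_z_max: float = 3.0):
    """Remove ratios whose replicates disagree too much.

    The error z-score standardizes each replicate error against the
    genome-wide error distribution of its method; removal is one-sided
    (concordant replicates are never removed). With all-zero errors (e.g.
    noise-free data) nothing is removed. Returns ``(removed_ids, error_z)``
    where error_z is indexed like ``ratios``.
    """
    err = ratios["replicate_error"]
    valid = err.notna()
    error_z = pd.Series(np.nan, index=ratios.index)
    removed: set = set()
    if valid.sum() == 0:
        return removed, error_z
    vals = err[valid].astype(float)
    sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
    if sd == 0:
        return removed, error_z
    error_z[valid] = (vals - vals.mean()) / sd
    mask = error_z > error_z_max
    removed = set(ratios.loc[mask & valid, "dsrna_id"])
    return removed, error_z


def stockplate_zscores(ratios: pd.DataFrame) -> pd.Series:
    """Standardize log2 ratios within each (method, stock plate) group.

    Uses the sample standard deviation (n−1). Groups smaller than 3 or
    with zero spread are rejected: they cannot define a distribution.
    """
    z = pd.Series(np.nan, index=ratios.index, name="z")
    for (method, plate), grp in ratios.groupby(["method", "stock_plate_id"], sort=False):
        vals = grp["log2_ratio"].astype(float)
        if len(vals) < 3:
            raise ValueError(
                f"stock-plate group ({method}, {plate}) has {len(vals)} records; need >= 3"
            )
        sd = vals.std(ddof=1)
        if sd <= 1e-12 * max(1.0, abs(vals.mean())):
            raise ValueError(f"stock-plate group ({method}, {plate}) has zero spread")
        z[grp.index] = (vals - vals.mean()) / sd
    return z


def call_hits(
    ratios: pd.DataFrame,
    thresholds: ThresholdConfig,
    annotations: pd.DataFrame,
) -> pd.DataFrame:
    """Call hits from z-scored ratio records (strict |z| > cutoff).

    Only records free of every removal flag are eligible. Returns one row
    per hit dsRNA with its gene, method, direction (LOW/HIGH) and z.
    """
    gene_of = annotations.set_index("dsrna_id")["gene_id"]
    rows = []
    for method in METHODS:
        cut = thresholds.z_cut(method)
        sub = ratios[(ratios["method"] == method) & ratios["z"].notna()]
        for rec in sub.itertuples(index=False):
            if abs(rec.z) > cut:
                rows.append(
                    (rec.dsrna_id, gene_of.get(rec.dsrna_id, rec.dsrna_id), method,
                     "LOW" if rec.z < 0 else "HIGH", rec.z)
                )
    return pd.DataFrame(rows, columns=["dsrna_id", "gene_id", "method", "direction", "z"])


def classify_overlap(hits: pd.DataFrame, ratios: pd.DataFrame | None = None,
                     annotations: pd.DataFrame | None = None) -> pd.DataFrame:
    """Intersect the two hit lists at the gene level.

    Genes hit by both normalization methods fall in area A, by BY_CON only
    in area B, by BY_M3 only in area C; the three areas partition the
    union of the hit lists. Multiple dsRNAs per gene are collapsed (a gene
    is a hit if any surviving dsRNA is); the reported z per method is the
    gene's most extreme surviving z.
    """
    by_con = set(hits.loc[hits["method"] == "BY_CON", "gene_id"])
    by_m3 = set(hits.loc[hits["method"] == "BY_M3", "gene_id"])
    extreme: dict[tuple[str, str], float] = {}
    if ratios is not None and annotations is not None and len(ratios):
        gene_of = annotations.set_index("dsrna_id")["gene_id"]
        scored = ratios[ratios["z"].notna()]
        for rec in scored.itertuples(index=False):
            key = (gene_of.get(rec.dsrna_id, rec.dsrna_id), rec.method)
            if key not in extreme or abs(rec.z) > abs(extreme[key]):
                extreme[key] = rec.z
    else:
        for rec in hits.itertuples(index=False):
            key = (rec.gene_id, rec.method)
            if key not in extreme or abs(rec.z) > abs(extreme[key]):
                extreme[key] = rec.z
    rows = []
    for gene in sorted(by_con | by_m3):
        if gene in by_con and gene in by_m3:
            area = "A"
        elif gene in by_con:
            area = "B"
        else:
            area = "C"
        rows.append(
            (gene, area, extreme.get((gene, "BY_CON"), np.nan),
             extreme.get((gene, "BY_M3"), np.nan))
        )
    return pd.DataFrame(rows, columns=["gene_id", "area", "z_con", "z_m3"])


class ScreenModel:
    """The screen analysis bound to its input tables.

    Parameters are the three canonical tables: a long-format measurement
    table, the plate map joining screening wells to dsRNAs and stock
    plates, and the dsRNA annotation table. ``fit`` runs the filter
    cascade and hit calling and returns a :class:`ScreenResults`.
    """

    def __init__(self, measurements, plate_map, annotations,
                 thresholds: ThresholdConfig | None = None):
        self.measurements = measurements
        self.plate_map = plate_map
        self.annotations = annotations
        self.thresholds = thresholds or ThresholdConfig()

    @classmethod
    def from_files(cls, measurements_path, plate_map_path, annotations_path,
                   thresholds: ThresholdConfig | None = None) -> "ScreenModel":
        from . import tables

        return cls(
            tables.read_measurements(measurements_path),
            tables.read_plate_map(plate_map_path),
            tables.read_annotations(annotations_path),
            thresholds,
        )

    def fit(self, thresholds: ThresholdConfig | None = None) -> "ScreenResults":
        th = thresholds or self.thresholds
        ann = self.annotations

        removed_ot, flagged_single = offtarget_filter(ann, th.max_offtargets)
        averaged = average_replicates(self.measurements, self.plate_map)
        all_ids = set(averaged["dsrna_id"].unique())
        surviving = all_ids - removed_ot

        con = averaged[(averaged["assay"] == "CON_LUC")
                       & averaged["dsrna_id"].isin(surviving)]
        con_means = con.set_index("dsrna_id")["mean_signal"]
        removed_via = viability_filter(con_means, th.viability_z_min)
        surviving -= removed_via

        report_rows = [
            ("offtarget", len(all_ids), len(removed_ot & all_ids)),
            ("viability", len(all_ids - removed_ot), len(removed_via)),
        ]

        keep = averaged[averaged["dsrna_id"].isin(surviving)]
        pieces = []
        for method in METHODS:
            rat = compute_ratios(keep, method)
            usable = rat["log2_ratio"].notna()
            removed_err, error_z = error_filter(rat[usable], th.error_z_max)
            rat["error_z"] = error_z.reindex(rat.index)
            rat["removed_error"] = rat["dsrna_id"].isin(removed_err)
            report_rows.append(
                (f"error_{method}", int(usable.sum()), len(removed_err))
            )
            scored_mask = usable & ~rat["removed_error"]
            rat["z"] = np.nan
            if scored_mask.any():
                rat.loc[scored_mask, "z"] = stockplate_zscores(rat[scored_mask])
            pieces.append(rat)
        ratios = pd.concat(pieces, ignore_index=True)

        # assemble the full record table, including removed dsRNAs
        gene_of = ann.set_index("dsrna_id")["gene_id"]
        full = []
        for method in METHODS:
            got = ratios[ratios["method"] == method].set_index("dsrna_id")
            for ds in sorted(all_ids):
                if ds in got.index:
                    r = got.loc[ds]
                    row = dict(
                        dsrna_id=ds, method=method,
                        stock_plate_id=r["stock_plate_id"],
                        log2_ratio=r["log2_ratio"], replicate_error=r["replicate_error"],
                        error_z=r["error_z"], z=r["z"],
                        nonpositive=bool(r["nonpositive"]),
                        incomplete=bool(r["incomplete"]),
                        removed_error=bool(r["removed_error"]),
                        removed_viability=False, removed_offtarget=False,
                    )
                else:
                    row = dict(
                        dsrna_id=ds, method=method, stock_plate_id="",
                        log2_ratio=np.nan, replicate_error=np.nan, error_z=np.nan,
                        z=np.nan, nonpositive=False, incomplete=False,
                        removed_error=False,
                        removed_viability=ds in removed_via,
                        removed_offtarget=ds in removed_ot,
                    )
                row["gene_id"] = gene_of.get(ds, ds)
                row["offtarget_single"] = ds in flagged_single
                full.append(row)
        records = pd.DataFrame(full)

        hits = call_hits(ratios, th, ann)
        overlap = classify_overlap(hits, ratios, ann)
        report = pd.DataFrame(report_rows, columns=["stage", "records_in", "removed"])
        report["fraction_removed"] = report["removed"] / report["records_in"]
        return ScreenResults(self, th, records, hits, overlap, report)


class ScreenResults:
    """Fitted screen analysis: z-scored ratio records, hit lists, overlap
    areas and the filter report."""

    def __init__(self, model, thresholds, ratio_records, hits, overlap, filter_report):
        self.model = model
        self.thresholds = thresholds
        self.ratio_records = ratio_records
        self.hits = hits
        self.overlap = overlap
        self.filter_report = filter_report

    def hit_genes(self, method: str | None = None) -> set:
        h = self.hits if method is None else self.hits[self.hits["method"] == method]
        return set(h["gene_id"])

    def hit_fraction(self, method: str) -> float:
        """Hits / scored records for one method (dsRNA level)."""
        rec = self.ratio_records
        scored = rec[(rec["method"] == method) & rec["z"].notna()]
        if not len(scored):
            return float("nan")
        return (self.hits["method"] == method).sum() / len(scored)

    def summary(self) -> str:
        th = self.thresholds
        buf = _io.StringIO()
        buf.write("Dual-normalization reporter screen\n")
        buf.write("==================================\n")
        buf.write(
            f"cutoffs: |z| > {th.z_cut_con} (BY_CON), |z| > {th.z_cut_m3} (BY_M3); "
            f"error z > {th.error_z_max}; viability z < {th.viability_z_min}; "
            f"off-targets > {th.max_offtargets} removed\n\n"
        )
        buf.write("Filter cascade:\n")
        for r in self.filter_report.itertuples(index=False):
            buf.write(
                f"  {r.stage:<14} in={r.records_in:<6} removed={r.removed:<5} "
                f"({100 * r.fraction_removed:.2f}%)\n"
            )
        buf.write("\nHits:\n")
        for method in METHODS:
            sub = self.hits[self.hits["method"] == method]
            low, high = (sub["direction"] == "LOW").sum(), (sub["direction"] == "HIGH").sum()
            buf.write(f"  {method:<7} LOW={low}  HIGH={high}  total={len(sub)}\n")
        counts = self.overlap["area"].value_counts()
        buf.write(
            "\nOverlap areas: A(both)={}  B(BY_CON only)={}  C(BY_M3 only)={}\n".format(
                counts.get("A", 0), counts.get("B", 0), counts.get("C", 0)
            )
        )
        return buf.getvalue()

    def to_directory(self, outdir) -> None:
        from pathlib import Path

        from . import tables

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        tables.write_table(self.ratio_records, out / "ratio_records.tsv")
        for method in METHODS:
            tables.write_table(
                self.hits[self.hits["method"] == method],
                out / f"hits_{method.lower()}.tsv",
            )
        tables.write_table(self.overlap, out / "overlap.tsv")
        tables.write_table(self.filter_report, out / "filter_report.tsv")
        (out / "summary.txt").write_text(self.summary())


def run_screen_pipeline(measurements, plate_map, annotations,
                        thresholds: ThresholdConfig | None = None) -> ScreenResults:
    """One-call wrapper: build a :class:`ScreenModel` and fit it."""
    return ScreenModel(measurements, plate_map, annotations, thresholds).fit()
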