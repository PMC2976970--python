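"""Quadruplicate four-condition retests and epistatic classification.

Candidate modifiers are retested under four transfection mixes: the
control promoter (con-luc), the uninduced reporter (m3-luc), and the
reporter induced by either the membrane-tethered receptor (NΔecn>m3-luc)
or its soluble intracellular domain (Nicd>m3-luc). Comparing the two
induced conditions separates factors acting at the membrane (receptor
processing) from factors acting downstream in the nucleus.

Reporter readings are first normalized by the same treatment's con-luc
mean (controlling for transfection efficiency and viability; switchable),
then each condition is compared against a null control-RNAi treatment by a
two-tailed two-sample t-test. Classes:

* I / II / III — both induced signals significantly decreased; split by the
  uninduced reporter effect (up / neutral / down). These genes promote
  Notch-dependent transcription downstream of receptor cleavage.
* IV — only the NΔecn-induced signal significantly increased: a repressor
  acting on the membrane-bound receptor (e.g. on intramembrane
  proteolysis).
* V — both induced signals significantly increased: a repressor acting on
  both receptor forms, i.e. downstream in the nucleus.
* UNCLASSIFIED — anything else.
"""

from __future__ import annotations

import io as _io

import numpy as np
import pandas as pd
from scipy import stats

from .tables import ASSAYS
from .simulate import CONTROL_GENE

CLASS_LABELS = ("I", "II", "III", "IV", "V", "UNCLASSIFIED")

#: conditions normalized by the treatment's con-luc mean
_REPORTER_CONDITIONS = ("M3_LUC", "NDELTA_M3", "NICD_M3")


def percent_deviation(gene_values, control_values) -> float:
    """Signed percent deviation of a treatment mean from the control mean:
    100 × (mean_gene − mean_control) / mean_control."""
    g = np.asarray(gene_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    if len(g) < 2 or len(c) < 2:
        raise ValueError("need at least 2 replicates per group")
    cm = c.mean()
    if cm == 0:
        raise ValueError("control mean is zero")
    return 100.0 * (g.mean() - cm) / cm


def ttest_vs_control(gene_values, control_values, equal_var: bool = True) -> float:
    """Two-tailed two-sample t-test p-value of a treatment against the
    control replicates (equal-variance by default; Welch optional).

    Degenerate zero-variance groups: equal means give p = 1 by convention;
    unequal means give the smallest positive float so that p stays in
    (0, 1].
    """
    g = np.asarray(gene_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    if len(g) < 2 or len(c) < 2:
        raise ValueError("need at least 2 replicates per group")
    if g.std() == 0 and c.std() == 0:
        return 1.0 if g.mean() == c.mean() else float(np.finfo(float).tiny)
    p = float(stats.ttest_ind(g, c, equal_var=equal_var).pvalue)
    if np.isnan(p):
        return 1.0
    return max(p, float(np.finfo(float).tiny))


NORMALIZATIONS = ("paired", "con_mean", "raw")


def normalize_readings(measurements: pd.DataFrame,
                       normalization: str = "paired") -> pd.DataFrame:
    """Attach con-luc-normalized reporter values (column ``value``).

    ``paired`` (default) divides each reporter reading (m3-luc,
    NΔecn>m3-luc, Nicd>m3-luc) by the same treatment's con-luc reading of
    the same replicate index, so the con normalization's own noise enters
    the within-group variance that the t-tests see — keeping the tests
    calibrated. ``con_mean`` divides by the treatment's con-luc mean
    instead (the normalization noise then shifts all replicates jointly
    and is invisible to the t-test); ``raw`` skips normalization. con-luc
    itself always stays on the raw scale.
    """
    if normalization not in NORMALIZATIONS:
        raise ValueError(f"normalization must be one of {NORMALIZATIONS}")
    df = measurements.copy()
    df["value"] = df["signal"].astype(float)
    if normalization == "raw":
        return df
    rep = df["condition"].isin(_REPORTER_CONDITIONS)
    con = df[df["condition"] == "CON_LUC"]
    if normalization == "con_mean":
        con_mean = con.groupby("gene_id")["signal"].mean()
        if (con_mean <= 0).any():
            bad = sorted(con_mean.index[con_mean <= 0])
            raise ValueError(f"non-positive con-luc mean for gene(s): {bad}")
        df.loc[rep, "value"] = (
            df.loc[rep, "signal"] / df.loc[rep, "gene_id"].map(con_mean)
        )
        return df
    paired = con.set_index(["gene_id", "replicate"])["signal"]
    if (paired <= 0).any():
        raise ValueError("non-positive con-luc reading; cannot normalize")
    idx = pd.MultiIndex.from_arrays([df.loc[rep, "gene_id"], df.loc[rep, "replicate"]])
    try:
        denom = paired.loc[idx].to_numpy()
    except KeyError as exc:
        raise ValueError(f"reporter replicate without a con-luc counterpart: {exc}")
    df.loc[rep, "value"] = df.loc[rep, "signal"].to_numpy() / denom
    return df


def build_profiles(measurements: pd.DataFrame, control_gene: str = CONTROL_GENE,
                   normalization: str = "paired",
                   equal_var: bool = True) -> pd.DataFrame:
    """Per (gene, condition) retest statistics.

    Returns mean signal, normalized mean, signed percent deviation from
    the control-RNAi treatment, SEM of the normalized values, and the
    two-tailed t-test p-value against the control replicates.
    """
    if control_gene not in set(measurements["gene_id"]):
        raise ValueError(f"control gene {control_gene!r} absent from measurements")
    df = normalize_readings(measurements, normalization)
    ctrl = df[df["gene_id"] == control_gene]
    ctrl_vals = {c: grp["value"].to_numpy() for c, grp in ctrl.groupby("condition")}
    rows = []
    for gene, grp in df.groupby("gene_id", sort=True):
        for cond in ASSAYS:
            vals = grp.loc[grp["condition"] == cond, "value"].to_numpy()
            if len(vals) == 0:
                raise ValueError(f"gene {gene}: missing condition {cond}")
            cv = ctrl_vals.get(cond)
            if cv is None:
                raise ValueError(f"control gene missing condition {cond}")
            rows.append(
                dict(
                    gene_id=gene,
                    condition=cond,
                    mean_signal=grp.loc[grp["condition"] == cond, "signal"].mean(),
                    mean_value=vals.mean(),
                    percent_deviation=percent_deviation(vals, cv),
                    sem=stats.sem(vals) if len(vals) > 1 else np.nan,
                    p_value=(1.0 if gene == control_gene
                             else ttest_vs_control(vals, cv, equal_var=equal_var)),
                )
            )
    return pd.DataFrame(rows)


def assign_epistatic_class(profile: pd.DataFrame, alpha: float = 0.05) -> str:
    """Assign the epistatic class from one gene's profile rows.

    ``profile`` holds that gene's four condition rows (percent_deviation,
    p_value). Significance is p < alpha; direction is the sign of the
    percent deviation. Every profile maps to exactly one label.
    """
    by_cond = profile.set_index("condition")
    missing = [c for c in ASSAYS if c not in by_cond.index]
    if missing:
        raise ValueError(f"missing condition(s): {missing}")

    def sig_down(cond):
        return by_cond.at[cond, "p_value"] < alpha and by_cond.at[cond, "percent_deviation"] < 0

    def sig_up(cond):
        return by_cond.at[cond, "p_value"] < alpha and by_cond.at[cond, "percent_deviation"] > 0

    if sig_down("NDELTA_M3") and sig_down("NICD_M3"):
        if sig_up("M3_LUC"):
            return "I"
        if sig_down("M3_LUC"):
            return "III"
        return "II"
    if sig_up("NDELTA_M3") and not sig_up("NICD_M3"):
        return "IV"
    if sig_up("NDELTA_M3") and sig_up("NICD_M3"):
        return "V"
    return "UNCLASSIFIED"


def retest_summary(positive_by_con, positive_by_m3, retested) -> dict:
    """Retest rates as integer percentages.

    Given the sets of genes significant under the con-luc-style and
    m3-luc-style contrasts and the full retested set, reports the percent
    positive by either method and by each method alone (rounded to the
    nearest integer, as 22 of 28 -> 79).
    """
    retested = set(retested)
    if not retested:
        raise ValueError("empty retest set")
    con = set(positive_by_con) & retested
    m3 = set(positive_by_m3) & retested
    n = len(retested)

    def pct(k):
        return int(round(100.0 * k / n))

    return {
        "n_retested": n,
        "either_percent": pct(len(con | m3)),
        "by_con_percent": pct(len(con)),
        "by_m3_percent": pct(len(m3)),
    }


class RetestModel:
    """Retest analysis bound to a quadruplicate measurement table.

    ``normalization`` is "paired" (each reporter reading divided by the
    same-replicate con-luc reading; default), "con_mean" (divided by the
    treatment's con-luc mean) or "raw"; ``equal_var`` selects the classic
    pooled t-test (Welch when off).
    """

    def __init__(self, measurements: pd.DataFrame, control_gene: str = CONTROL_GENE,
                 alpha: float = 0.05, normalization: str = "paired",
                 equal_var: bool = True):
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if normalization not in NORMALIZATIONS:
            raise ValueError(f"normalization must be one of {NORMALIZATIONS}")
        self.measurements = measurements
        self.control_gene = control_gene
        self.alpha = alpha
        self.normalization = normalization
        self.equal_var = equal_var

    @classmethod
    def from_file(cls, path, **kwargs) -> "RetestModel":
        from . import tables

        return cls(tables.read_retest_measurements(path), **kwargs)

    def fit(self) -> "RetestResults":
        profiles = build_profiles(
            self.measurements, self.control_gene,
            normalization=self.normalization, equal_var=self.equal_var,
        )
        rows = []
        for gene, grp in profiles.groupby("gene_id", sort=True):
            if gene == self.control_gene:
                continue
            rows.append((gene, assign_epistatic_class(grp, self.alpha)))
        classes = pd.DataFrame(rows, columns=["gene_id", "label"])
        return RetestResults(self, profiles, classes)


class RetestResults:
    """Fitted retest analysis: per-condition profiles and class labels."""

    def __init__(self, model: RetestModel, profiles: pd.DataFrame, classes: pd.DataFrame):
        self.model = model
        self.profiles = profiles
        self.classes = classes

    def positives_by_method(self) -> tuple[set, set]:
        """Genes whose induced signal retests significant under each
        normalization contrast.

        BY_CON-style: NΔecn>m3-luc normalized by con-luc (the default
        profile test). BY_M3-style: NΔecn readings normalized by the same
        treatment's uninduced m3-luc reading (replicate-paired), tested
        against the control.
        """
        m = self.model
        alpha = m.alpha
        df = m.measurements
        con_positive = set(
            self.profiles.loc[
                (self.profiles["condition"] == "NDELTA_M3")
                & (self.profiles["p_value"] < alpha)
                & (self.profiles["gene_id"] != m.control_gene),
                "gene_id",
            ]
        )
        m3 = df[df["condition"] == "M3_LUC"].set_index(["gene_id", "replicate"])["signal"]
        nd = df[df["condition"] == "NDELTA_M3"].copy()
        denom = m3.loc[
            pd.MultiIndex.from_arrays([nd["gene_id"], nd["replicate"]])
        ].to_numpy()
        nd["value"] = nd["signal"].to_numpy() / denom
        ctrl = nd.loc[nd["gene_id"] == m.control_gene, "value"].to_numpy()
        m3_positive = set()
        for gene, grp in nd.groupby("gene_id"):
            if gene == m.control_gene:
                continue
            if ttest_vs_control(grp["value"].to_numpy(), ctrl, m.equal_var) < alpha:
                m3_positive.add(gene)
        return con_positive, m3_positive

    def rates(self) -> dict:
        """Integer-percent retest rates (either / by method)."""
        con, m3 = self.positives_by_method()
        genes = set(self.classes["gene_id"])
        return retest_summary(con, m3, genes)

    def summary(self) -> str:
        buf = _io.StringIO()
        buf.write("Four-condition retest analysis\n")
        buf.write("==============================\n")
        buf.write(f"alpha = {self.model.alpha}; control = {self.model.control_gene}\n\n")
        counts = self.classes["label"].value_counts()
        for label in CLASS_LABELS:
            if counts.get(label, 0):
                genes = ", ".join(
                    self.classes.loc[self.classes["label"] == label, "gene_id"]
                )
                buf.write(f"  class {label:<12} n={counts[label]:<3} ({genes})\n")
        r = self.rates()
        buf.write(
            f"\nretested positive: {r['either_percent']}% by either contrast "
            f"({r['by_m3_percent']}% by m3-luc, {r['by_con_percent']}% by con-luc; "
            f"n={r['n_retested']})\n"
        )
        return buf.getvalue()

    def to_directory(self, outdir) -> None:
        from pathlib import Path

        from . import tables

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        tables.write_table(self.profiles, out / "retest_profiles.tsv")
        tables.write_table(self.classes, out / "retest_classes.tsv")
        (out / "retest_summary.txt").write_text(self.summary())
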