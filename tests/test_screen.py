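"""Scoring pipeline: averaging, filters, stock-plate z-scores, hit calling."""

import numpy as np
import pandas as pd
import pytest

from notchscreen import ScreenModel, ThresholdConfig
from notchscreen import simulate as sim
from notchscreen.screen import (
    average_replicates,
    call_hits,
    classify_overlap,
    compute_ratios,
    error_filter,
    offtarget_filter,
    stockplate_zscores,
    viability_filter,
)


def _signals_frame(rows):
    """rows: (dsrna_id, assay, copy_1, copy_2)."""
    df = pd.DataFrame(rows, columns=["dsrna_id", "assay", "copy_1", "copy_2"])
    df["stock_plate_id"] = "ST01"
    df["mean_signal"] = df[["copy_1", "copy_2"]].mean(axis=1)
    df["n_obs"] = df[["copy_1", "copy_2"]].notna().sum(axis=1)
    df["incomplete"] = df["n_obs"] < 2
    return df


# --- averaging -------------------------------------------------------------

def test_average_replicates_mean_and_incomplete():
    pm = pd.DataFrame(
        {"screen_plate_id": ["SP01"] * 2, "well": ["A01", "A02"],
         "dsrna_id": ["d1", "d2"], "stock_plate_id": ["ST01"] * 2,
         "stock_well": ["A01", "A02"]}
    )
    meas = pd.DataFrame(
        {"assay": ["CON_LUC"] * 3, "plate_copy": [1, 2, 1],
         "screen_plate_id": ["SP01"] * 3, "well": ["A01", "A01", "A02"],
         "signal": [100.0, 300.0, 50.0]}
    )
    avg = average_replicates(meas, pm).set_index("dsrna_id")
    assert avg.at["d1", "mean_signal"] == 200.0 and not avg.at["d1", "incomplete"]
    assert avg.at["d2", "mean_signal"] == 50.0 and avg.at["d2", "incomplete"]


def test_average_replicates_unmapped_well_rejected():
    pm = pd.DataFrame(
        {"screen_plate_id": ["SP01"], "well": ["A01"], "dsrna_id": ["d1"],
         "stock_plate_id": ["ST01"], "stock_well": ["A01"]}
    )
    meas = pd.DataFrame(
        {"assay": ["CON_LUC"], "plate_copy": [1], "screen_plate_id": ["SP01"],
         "well": ["B05"], "signal": [1.0]}
    )
    with pytest.raises(ValueError, match="SP01:B05"):
        average_replicates(meas, pm)


def test_zero_noise_averages_equal_baselines():
    cfg = sim.SimulationConfig(n_stock_plates=1, noise_sigma=0.0, seed=0)
    pm, meas, _ = sim.generate_screen(cfg)
    avg = average_replicates(meas, pm)
    for assay, base in (("CON_LUC", cfg.baseline_con), ("M3_LUC", cfg.baseline_m3),
                        ("NDELTA_M3", cfg.baseline_ndelta)):
        assert (avg.loc[avg["assay"] == assay, "mean_signal"] == base).all()


# --- ratios ----------------------------------------------------------------

def test_log2_ratio_and_replicate_error():
    sig = _signals_frame([
        ("d1", "NDELTA_M3", 800.0, 800.0), ("d1", "CON_LUC", 200.0, 200.0),
        ("d2", "NDELTA_M3", 400.0, 100.0), ("d2", "CON_LUC", 100.0, 100.0),
        ("d3", "NDELTA_M3", 0.0, 0.0), ("d3", "CON_LUC", 100.0, 100.0),
    ])
    rat = compute_ratios(sig, "BY_CON").set_index("dsrna_id")
    assert rat.at["d1", "log2_ratio"] == 2.0  # log2(800/200)
    assert rat.at["d1", "replicate_error"] == 0.0
    assert rat.at["d2", "replicate_error"] == 2.0  # |log2 4 - log2 1|
    assert np.isnan(rat.at["d3", "log2_ratio"]) and rat.at["d3", "nonpositive"]


def test_zero_noise_ratio_identity():
    """With sigma=0 the log2 ratio is exactly log2(baseline x multiplier ratio)."""
    prof = sim.EffectProfile("eff", mult_m3_ndelta=0.25)
    cfg = sim.SimulationConfig(n_stock_plates=1, noise_sigma=0.0, seed=0,
                               spike_table=(prof,))
    pm, meas, ann = sim.generate_screen(cfg)
    rat = compute_ratios(average_replicates(meas, pm), "BY_CON")
    rat = rat.merge(ann[["dsrna_id", "gene_id"]], on="dsrna_id")
    expected_null = np.log2(cfg.baseline_ndelta / cfg.baseline_con)
    eff = rat["gene_id"] == "eff"
    assert (rat.loc[~eff, "log2_ratio"] == expected_null).all()
    assert rat.loc[eff, "log2_ratio"].iloc[0] == expected_null + np.log2(0.25)


# --- filters ---------------------------------------------------------------

def test_offtarget_rule():
    ann = pd.DataFrame(
        {"dsrna_id": ["d0", "d1", "d2"], "gene_id": list("abc"),
         "gene_symbol": list("abc"), "offtarget_count": [0, 1, 2]}
    )
    removed, flagged = offtarget_filter(ann, max_offtargets=1)
    assert removed == {"d2"} and flagged == {"d1"}
    removed, flagged = offtarget_filter(ann.assign(offtarget_count=0), 1)
    assert removed == set() and flagged == set()


def test_viability_filter_extreme_outlier_and_one_sidedness():
    rng = np.random.default_rng(0)
    vals = pd.Series(
        np.r_[100 * np.exp(0.01 * rng.normal(size=99)), 1.0, 1e4],
        index=[f"d{i}" for i in range(101)],
    )
    removed = viability_filter(vals, -2.0)
    assert "d99" in removed       # 100-fold low outlier removed
    assert "d100" not in removed  # bright wells never removed


def test_viability_filter_degenerate_rejected():
    with pytest.raises(ValueError, match="zero spread"):
        viability_filter(pd.Series([10.0] * 50, index=[f"d{i}" for i in range(50)]))
    with pytest.raises(ValueError, match="at least 3"):
        viability_filter(pd.Series([1.0, 2.0], index=["a", "b"]))


def test_error_filter_identical_replicates_no_removals():
    rat = pd.DataFrame(
        {"dsrna_id": [f"d{i}" for i in range(10)], "method": "BY_CON",
         "replicate_error": 0.0}
    )
    removed, _ = error_filter(rat, 3.0)
    assert removed == set()


def test_error_filter_extreme_discordance_removed():
    errs = [0.1] * 50 + [0.11] * 49 + [6.6]  # ~100-fold replicate disagreement
    rat = pd.DataFrame(
        {"dsrna_id": [f"d{i}" for i in range(100)], "method": "BY_CON",
         "replicate_error": errs}
    )
    removed, error_z = error_filter(rat, 3.0)
    assert removed == {"d99"}
    assert (error_z.dropna() <= error_z.max()).all()


def test_filter_monotonicity(null_screen):
    """Stricter cutoffs only grow the removal sets."""
    _, pm, meas, ann = null_screen
    loose = ScreenModel(meas, pm, ann, ThresholdConfig()).fit()
    strict = ScreenModel(
        meas, pm, ann, ThresholdConfig(error_z_max=2.0, viability_z_min=-1.5)
    ).fit()

    def removed(res, col):
        r = res.ratio_records
        return set(r.loc[r[col], "dsrna_id"])

    assert removed(loose, "removed_viability") <= removed(strict, "removed_viability")
    assert removed(loose, "removed_error") <= removed(strict, "removed_error")


# --- z-scores --------------------------------------------------------------

def test_stockplate_z_simple_group():
    rat = pd.DataFrame(
        {"dsrna_id": ["a", "b", "c"], "method": "BY_CON",
         "stock_plate_id": "ST01", "log2_ratio": [1.0, 2.0, 3.0]}
    )
    z = stockplate_zscores(rat)
    assert z.iloc[2] == pytest.approx(1.0)  # mean 2, sample sd 1
    assert z.iloc[1] == 0.0                 # value at the group mean


def test_stockplate_z_degenerate_groups_rejected():
    small = pd.DataFrame(
        {"dsrna_id": ["a", "b"], "method": "BY_CON", "stock_plate_id": "ST01",
         "log2_ratio": [1.0, 2.0]}
    )
    with pytest.raises(ValueError, match="need >= 3"):
        stockplate_zscores(small)
    flat = pd.DataFrame(
        {"dsrna_id": list("abc"), "method": "BY_CON", "stock_plate_id": "ST01",
         "log2_ratio": [1.0, 1.0, 1.0]}
    )
    with pytest.raises(ValueError, match="zero spread"):
        stockplate_zscores(flat)


def test_stockplate_z_matches_brute_force(null_result):
    """Oracle: an explicit per-group loop reproduces every z to 1e-9, and
    each group standardizes to mean 0, sd 1."""
    rec = null_result.ratio_records
    scored = rec[rec["z"].notna()]
    for (_, _), grp in scored.groupby(["method", "stock_plate_id"]):
        vals = grp["log2_ratio"].to_numpy()
        mu = sum(vals) / len(vals)
        sd = (sum((v - mu) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
        brute = (vals - mu) / sd
        assert np.allclose(grp["z"].to_numpy(), brute, atol=1e-9)
        assert abs(np.mean(grp["z"])) < 1e-9
        assert abs(np.std(grp["z"], ddof=1) - 1) < 1e-9


# --- hit calling and overlap ----------------------------------------------

def test_hit_cutoffs_are_method_specific_and_strict():
    ann = pd.DataFrame(
        {"dsrna_id": ["d1", "d2", "d3"], "gene_id": list("abc"),
         "gene_symbol": list("abc"), "offtarget_count": 0}
    )
    rat = pd.DataFrame(
        {"dsrna_id": ["d1", "d1", "d2", "d3"],
         "method": ["BY_M3", "BY_CON", "BY_CON", "BY_M3"],
         "z": [1.9, 1.9, -2.5, 1.8]}
    )
    hits = call_hits(rat, ThresholdConfig(), ann)
    keyed = set(zip(hits["dsrna_id"], hits["method"]))
    assert ("d1", "BY_M3") in keyed        # 1.9 > 1.8 cutoff
    assert ("d1", "BY_CON") not in keyed   # 1.9 < 2.0 cutoff
    assert ("d3", "BY_M3") not in keyed    # strict: 1.8 is not > 1.8
    low = hits[hits["dsrna_id"] == "d2"]
    assert low["direction"].iloc[0] == "LOW"


def test_overlap_partition_algebra():
    """Areas: A = both-method genes; A|B = BY_CON set; A|C = BY_M3 set."""
    rng = np.random.default_rng(1)
    genes = [f"g{i}" for i in range(40)]
    rows = []
    for g in genes:
        if rng.random() < 0.5:
            rows.append((g, g, "BY_CON", "HIGH", 2.5))
        if rng.random() < 0.5:
            rows.append((g, g, "BY_M3", "LOW", -2.2))
    hits = pd.DataFrame(rows, columns=["dsrna_id", "gene_id", "method",
                                       "direction", "z"])
    ov = classify_overlap(hits)
    con = set(hits.loc[hits["method"] == "BY_CON", "gene_id"])
    m3 = set(hits.loc[hits["method"] == "BY_M3", "gene_id"])
    area = {a: set(ov.loc[ov["area"] == a, "gene_id"]) for a in "ABC"}
    assert area["A"] == con & m3
    assert area["A"] | area["B"] == con and area["A"] | area["C"] == m3
    assert len(ov) == len(con | m3)  # mutually exclusive and exhaustive


# --- end-to-end ------------------------------------------------------------

def test_canonical_controls_pipeline(controls_result):
    res = controls_result
    ov = res.overlap.set_index("gene_id")
    assert ov.at["SuH_like", "area"] == "A" and ov.at["SuH_like", "z_con"] < 0
    mam = res.hits[res.hits["gene_id"] == "mam_like"]
    assert set(mam["method"]) == {"BY_CON", "BY_M3"}
    assert (mam["direction"] == "LOW").all()
    # the decoy's effect is as strong as mam's, but two predicted
    # off-targets exclude it from every list
    assert "decoy_offtarget" not in set(res.hits["gene_id"])
    assert "decoy_offtarget" not in set(res.overlap["gene_id"])
    # an H-like gene that survives the filters is a BY_M3 hit only
    rec = res.ratio_records
    h = rec[(rec["gene_id"] == "H_like") & (rec["method"] == "BY_M3")]
    if h["z"].notna().all():
        assert ov.at["H_like", "area"] == "C"


def test_filter_report_bookkeeping(controls_result):
    report = controls_result.filter_report.set_index("stage")
    n_total = report.at["offtarget", "records_in"]
    assert report.at["viability", "records_in"] == \
        n_total - report.at["offtarget", "removed"]
    surviving = report.at["viability", "records_in"] - report.at["viability", "removed"]
    for method in ("BY_CON", "BY_M3"):
        stage = report.loc[f"error_{method}"]
        assert stage["records_in"] <= surviving
        rec = controls_result.ratio_records
        scored = rec[(rec["method"] == method) & rec["z"].notna()]
        assert len(scored) == stage["records_in"] - stage["removed"]
    assert (report["fraction_removed"] ==
            report["removed"] / report["records_in"]).all()


def test_summary_mentions_thresholds(controls_result):
    text = controls_result.summary()
    assert "1.8" in text and "2.0" in text and "Overlap areas" in text
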