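"""Synthetic screen and retest data with known ground truth.

The generator emulates the structure of a genome-wide dual-luciferase RNAi
screen: one dsRNA per well of 96-well stock plates, four stock plates
interleaved by quadrant into one 384-well screening plate, and each
screening plate read under three transfection conditions (con-luc control
promoter, uninduced m3-luc reporter, NΔecn-induced m3-luc reporter) in
duplicate. Retests add the fourth, Nicd-induced condition in quadruplicate.

Signals are multiplicative-lognormal: signal = baseline × effect multiplier
× exp(N(0, σ²)), with the biological effect applied identically to every
replicate and technical noise drawn independently per replicate. A single
integer seed fully determines the output; wells are iterated sorted by
stock plate, row, column.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .tables import ASSAYS, SCREEN_ASSAYS, rc_to_well

#: condition label -> EffectProfile multiplier attribute
_MULT_ATTR = {
    "CON_LUC": "mult_con",
    "M3_LUC": "mult_m3_uninduced",
    "NDELTA_M3": "mult_m3_ndelta",
    "NICD_M3": "mult_m3_nicd",
}

CONTROL_GENE = "control_RNAi"


@dataclass(frozen=True)
class EffectProfile:
    """Ground-truth effect of knocking down one gene.

    Multipliers scale the four assay baselines; a profile of all 1.0 is a
    null gene, and a viability profile applies the same sub-unity
    multiplier to all four signals. ``discordant`` restricts the effect to
    the first replicate only, emulating an irreproducible well that the
    replicate-error filter should catch.
    """

    gene_id: str
    mult_con: float = 1.0
    mult_m3_uninduced: float = 1.0
    mult_m3_ndelta: float = 1.0
    mult_m3_nicd: float = 1.0
    offtarget_count: int = 0
    go_class: str = ""
    localization: str = "unknown"
    discordant: bool = False

    def __post_init__(self):
        for attr in _MULT_ATTR.values():
            if not getattr(self, attr) > 0:
                raise ValueError(f"{self.gene_id}: {attr} must be strictly positive")
        if self.offtarget_count < 0:
            raise ValueError(f"{self.gene_id}: offtarget_count must be >= 0")

    def multiplier(self, condition: str) -> float:
        return getattr(self, _MULT_ATTR[condition])


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic screen.

    Baselines are median luminescence in arbitrary units; induction must
    raise the reporter (baseline_ndelta > baseline_m3). noise_sigma is the
    standard deviation of the natural-log multiplicative noise.
    """

    n_stock_plates: int = 4
    wells_per_stock: int = 96
    baseline_con: float = 20000.0
    baseline_m3: float = 500.0
    baseline_ndelta: float = 10000.0
    baseline_nicd: float = 8000.0
    noise_sigma: float = 0.2
    n_replicates: int = 2
    spike_table: tuple[EffectProfile, ...] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "spike_table", tuple(self.spike_table))
        for name in ("baseline_con", "baseline_m3", "baseline_ndelta", "baseline_nicd"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.baseline_ndelta <= self.baseline_m3:
            raise ValueError("baseline_ndelta must exceed baseline_m3 (induction)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_stock_plates < 1 or self.n_replicates < 1:
            raise ValueError("n_stock_plates and n_replicates must be >= 1")
        if self.wells_per_stock % 8 != 0 or not 8 <= self.wells_per_stock <= 96:
            raise ValueError("wells_per_stock must be a multiple of 8, at most 96")
        ids = [p.gene_id for p in self.spike_table]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate gene_ids in spike table")

    @property
    def baselines(self) -> dict[str, float]:
        return {
            "CON_LUC": self.baseline_con,
            "M3_LUC": self.baseline_m3,
            "NDELTA_M3": self.baseline_ndelta,
            "NICD_M3": self.baseline_nicd,
        }


def _stock_wells(config: SimulationConfig):
    """All (stock_plate_index, row, col) in fixed iteration order."""
    n_cols = config.wells_per_stock // 8
    return [
        (sp, r, c)
        for sp in range(config.n_stock_plates)
        for r in range(8)
        for c in range(n_cols)
    ]


def _screen_position(sp: int, r: int, c: int) -> tuple[int, int, int]:
    """Quadrant interleave: stock well (r, c) of the q-th stock plate in a
    group of four maps to screening-plate well (2r + q//2, 2c + q%2)."""
    q = sp % 4
    return sp // 4, 2 * r + q // 2, 2 * c + q % 2


def _assign_profiles(config: SimulationConfig, n_wells: int):
    """Place spike profiles at evenly spaced well indices (deterministic,
    independent of the noise stream); all other wells get null genes."""
    spikes = config.spike_table
    if len(spikes) > n_wells:
        raise ValueError("more spike profiles than wells")
    profiles: list[EffectProfile | None] = [None] * n_wells
    if spikes:
        idx = np.unique(np.linspace(0, n_wells - 1, len(spikes)).round().astype(int))
        if len(idx) < len(spikes):  # tiny plates: fall back to the first wells
            idx = np.arange(len(spikes))
        for i, prof in zip(idx, spikes):
            profiles[int(i)] = prof
    return profiles


def generate_screen(config: SimulationConfig):
    """Generate one synthetic screen.

    Returns ``(plate_map, measurements, annotations)`` as DataFrames in the
    canonical table schemas. Identical configs (same seed) yield identical
    tables.
    """
    rng = np.random.default_rng(config.seed)
    wells = _stock_wells(config)
    n_wells = len(wells)
    profiles = _assign_profiles(config, n_wells)

    noise = rng.normal(size=(n_wells, len(SCREEN_ASSAYS), config.n_replicates))

    pm_rows, meas_rows, ann_rows = [], [], []
    null_counter = 0
    for w, (sp, r, c) in enumerate(wells):
        prof = profiles[w]
        if prof is None:
            null_counter += 1
            gene_id, offtargets, go, loc = f"CG{30000 + null_counter}", 0, "", "unknown"
        else:
            gene_id, offtargets = prof.gene_id, prof.offtarget_count
            go, loc = prof.go_class, prof.localization
        dsrna_id = f"DRC{w + 1:05d}"
        plate, rr, cc = _screen_position(sp, r, c)
        screen_plate = f"SP{plate + 1:02d}"
        screen_well = rc_to_well(rr, cc, 384)
        pm_rows.append(
            (screen_plate, screen_well, dsrna_id, f"ST{sp + 1:02d}", rc_to_well(r, c, 96))
        )
        ann_rows.append((dsrna_id, gene_id, gene_id, offtargets, go, loc))
        for a, assay in enumerate(SCREEN_ASSAYS):
            base = config.baselines[assay]
            for k in range(config.n_replicates):
                mult = 1.0
                if prof is not None and (not prof.discordant or k == 0):
                    mult = prof.multiplier(assay)
                signal = base * mult * np.exp(config.noise_sigma * noise[w, a, k])
                meas_rows.append((assay, k + 1, screen_plate, screen_well, signal))

    plate_map = pd.DataFrame(
        pm_rows,
        columns=["screen_plate_id", "well", "dsrna_id", "stock_plate_id", "stock_well"],
    )
    measurements = pd.DataFrame(
        meas_rows, columns=["assay", "plate_copy", "screen_plate_id", "well", "signal"]
    )
    annotations = pd.DataFrame(
        ann_rows,
        columns=["dsrna_id", "gene_id", "gene_symbol", "offtarget_count", "go_class",
                 "localization"],
    )
    return plate_map, measurements, annotations


def spike_canonical_controls(
    config: SimulationConfig, strength: float = 4.0
) -> SimulationConfig:
    """Append the canonical control profiles to a config.

    Emulates the known-component validation set: a Su(H)-like gene
    (opposing effects: induced signal down, uninduced reporter de-repressed),
    a mam-like coactivator (induced signal down only), an H-like repressor
    (uninduced reporter up only), a viability profile (all signals down
    jointly), and a decoy carrying two predicted off-targets that the
    off-target filter must exclude no matter how strong its effect.
    """
    if strength <= 1:
        raise ValueError("strength must exceed 1")
    lo, hi = 1.0 / strength, strength
    controls = (
        EffectProfile("SuH_like", mult_m3_uninduced=hi, mult_m3_ndelta=lo,
                      mult_m3_nicd=lo, go_class="transcription factor",
                      localization="nuclear"),
        EffectProfile("mam_like", mult_m3_ndelta=lo, mult_m3_nicd=lo,
                      go_class="transcription factor", localization="nuclear"),
        EffectProfile("H_like", mult_m3_uninduced=hi,
                      go_class="transcription factor", localization="nuclear"),
        EffectProfile("viability_like", mult_con=lo, mult_m3_uninduced=lo,
                      mult_m3_ndelta=lo, mult_m3_nicd=lo),
        EffectProfile("decoy_offtarget", mult_m3_ndelta=lo, mult_m3_nicd=lo,
                      offtarget_count=2),
    )
    existing = {p.gene_id for p in config.spike_table}
    clash = existing & {p.gene_id for p in controls}
    if clash:
        raise ValueError(f"spike name collision: {sorted(clash)}")
    return replace(config, spike_table=config.spike_table + controls)


CANONICAL_CONTROL_GENES = ("SuH_like", "mam_like", "H_like", "viability_like",
                           "decoy_offtarget")


def generate_retest(config: SimulationConfig, genes: Sequence[str]) -> pd.DataFrame:
    """Generate quadruplicate four-condition retest measurements.

    Each listed gene (looked up in the spike table; unknown genes are
    treated as null) plus a null control-RNAi gene is measured four times
    under each of con-luc, m3-luc, NΔecn>m3-luc and Nicd>m3-luc.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty retest gene list")
    if len(genes) != len(set(genes)):
        raise ValueError("duplicate genes in retest list")
    n_rep = 4
    by_id = {p.gene_id: p for p in config.spike_table}
    all_genes = genes + ([CONTROL_GENE] if CONTROL_GENE not in genes else [])
    rng = np.random.default_rng(config.seed)
    noise = rng.normal(size=(len(all_genes), len(ASSAYS), n_rep))
    rows = []
    for g, gene in enumerate(all_genes):
        prof = by_id.get(gene)
        for a, cond in enumerate(ASSAYS):
            base = config.baselines[cond]
            mult = prof.multiplier(cond) if prof is not None else 1.0
            for k in range(n_rep):
                m = mult if (prof is None or not prof.discordant or k == 0) else 1.0
                signal = base * m * np.exp(config.noise_sigma * noise[g, a, k])
                rows.append((gene, cond, k + 1, signal))
    return pd.DataFrame(rows, columns=["gene_id", "condition", "replicate", "signal"])


def generate_interactions(
    gene_ids: Sequence[str],
    core_genes: Sequence[str],
    n_edges: int,
    seed: int = 0,
    extra_genes: int = 20,
) -> pd.DataFrame:
    """Random physical-interaction edges over genes, core pathway nodes and
    a pool of bystander genes (so induced subgraphs have edges to drop).

    Artifact plumbing for fully simulated end-to-end runs; real analyses
    load a curated interaction table instead.
    """
    rng = np.random.default_rng(seed)
    pool = list(dict.fromkeys(list(core_genes) + list(gene_ids)))
    pool += [f"BYSTANDER{i + 1:03d}" for i in range(extra_genes)]
    if len(pool) < 2:
        raise ValueError("need at least two genes to draw edges")
    edges: dict[tuple[str, str], str] = {}
    # anchor: connect each core gene to one screen gene where possible
    targets = [g for g in gene_ids if g not in core_genes]
    for cg in core_genes:
        if targets:
            partner = targets[int(rng.integers(len(targets)))]
            edges[tuple(sorted((cg, partner)))] = "synthetic"
    attempts = 0
    while len(edges) < n_edges and attempts < 50 * n_edges:
        attempts += 1
        i, j = rng.integers(len(pool)), rng.integers(len(pool))
        if i == j:
            continue
        edges[tuple(sorted((pool[int(i)], pool[int(j)])))] = "synthetic"
    rows = [(a, b, tag) for (a, b), tag in sorted(edges.items())]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "source_tag"])
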