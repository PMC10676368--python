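"""End-to-end orchestration of the two study arms.

The phylogenetic arm harmonizes the audiogram compilation to
speaker-reference AT18m values, fits the ten evolutionary scenarios on
the time-calibrated tree under one chimpanzee-audiogram assumption,
selects the best by AICc and reconstructs ancestral states.  The
transfer-function arm builds per-specimen EMTF curves, compares species
groups frequency-wise, and regresses the measured human/chimp
differences against the published candidate difference sets.

Both arms return JSON-serializable reports with provenance (input
hashes or generating seed, package version).
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, audiograms as ag, delta as dl, phylo, synth, transfer as tf
from .trees import as_tree_arrays

__all__ = ["RunConfig", "run_phylo_arm", "run_emtf_arm", "select_chimp_variant",
           "write_report"]

log = logging.getLogger("earevol")

SCENARIO_COUNT = 10  # BM, BMS x 1-4 shifts, lambda, delta, kappa, OU, ACDC


@dataclass
class RunConfig:
    """Inputs for one full run.

    Any path left as None falls back to the packaged synthetic
    fixtures, generated from ``seed``.  ``chimp_variant`` selects which
    of the two published chimpanzee audiograms enters the phylogenetic
    arm ('elder' or 'kojima').
    """
    tree_path: str = None
    audiogram_path: str = None
    frf_path: str = None
    gain_paths: dict = field(default_factory=dict)   # species -> path
    chimp_variant: str = "elder"
    seed: int = 20231125
    outdir: str = None

    def __post_init__(self):
        if self.chimp_variant not in ("elder", "kojima"):
            raise ValueError("chimp_variant must be 'elder' or 'kojima'")
        for p in [self.tree_path, self.audiogram_path, self.frf_path,
                  *self.gain_paths.values()]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _provenance(config: RunConfig, paths):
    prov = {"version": __version__, "seed": config.seed}
    for name, p in paths.items():
        if p is None:
            prov[name] = f"synthetic(seed={config.seed})"
        else:
            prov[name] = "sha256:" + hashlib.sha256(
                Path(p).read_bytes()).hexdigest()[:16]
    return prov


def select_chimp_variant(audiogram_list, variant):
    """Keep a single chimpanzee speaker audiogram matching the variant."""
    out = []
    for a in audiogram_list:
        if a.species == "Pan troglodytes" and a.method == "speaker":
            if variant in a.source:
                out.append(a)
        else:
            out.append(a)
    return out


def run_phylo_arm(config: RunConfig) -> dict:
    """Harmonize -> AT18m -> fit 10 scenarios -> AICc-select -> ancestral
    states, under the configured chimpanzee-audiogram assumption."""
    ta = as_tree_arrays(str(config.tree_path)) if config.tree_path \
        else synth.make_fixture_tree()
    table = config.audiogram_path or synth.make_fixture_audiograms(config.seed)
    auds = select_chimp_variant(ag.load_audiograms(table), config.chimp_variant)
    log.info("phylo arm: %d audiograms, %d tips, variant=%s",
             len(auds), ta.n_tips, config.chimp_variant)

    traits, diagnostics = ag.harmonize(auds)
    missing = sorted(set(ta.tip_labels) - set(traits))
    if missing:
        raise ValueError(f"stage harmonize: no AT18m for tips {missing}")

    try:
        fits = phylo.fit_all_scenarios(ta, traits)
    except Exception as e:
        raise RuntimeError(f"stage model-fitting failed: {e}") from e
    assert len(fits) == SCENARIO_COUNT
    order = np.argsort([f.aicc for f in fits])
    best = fits[int(order[0])]
    amin = best.aicc
    scenarios = []
    for f in fits:
        d = f.to_dict()
        d["delta_aicc"] = f.aicc - amin
        scenarios.append(d)
    w = np.exp(-0.5 * np.array([d["delta_aicc"] for d in scenarios]))
    for d, wi in zip(scenarios, w / w.sum()):
        d["akaike_weight"] = float(wi)

    anc = phylo.ancestral_states(ta, traits, best)
    lca_est, lca_var = anc.at_mrca(["Homo sapiens", "Pan troglodytes"])
    report = {
        "arm": "phylo",
        "variant": config.chimp_variant,
        "provenance": _provenance(config, {"tree": config.tree_path,
                                           "audiograms": config.audiogram_path}),
        "n_species": len(traits),
        "at18m_db": {k: round(v, 4) for k, v in sorted(traits.items())},
        "correction_mean_abr_db": diagnostics["mean_abr_offset_db"],
        "correction_mean_headphone_db": diagnostics["mean_headphone_offset_db"],
        "scenarios": scenarios,
        "winner": scenarios[int(order[0])],
        "ancestral_states": {"+".join(k): {"estimate_db": e, "variance_db2": v}
                             for k, (e, v) in anc.by_key().items()
                             if len(k) > 1},
        "homo_pan_lca_at18m_db": lca_est,
        "homo_pan_lca_variance_db2": lca_var,
    }
    if config.outdir:
        write_report(report, Path(config.outdir) /
                     f"phylo_{config.chimp_variant}.json")
    return report


def _load_gains(config: RunConfig, species):
    gains = {}
    for sp in species:
        if sp in config.gain_paths:
            gains[sp] = pd.read_csv(config.gain_paths[sp])
        else:
            gains[sp] = synth.make_fixture_gain(sp)
    return gains


def run_emtf_arm(config: RunConfig) -> dict:
    """FRF frames -> EMTF curves -> features -> group comparison ->
    difference-set regressions with AICc evidence ratios."""
    frf = pd.read_csv(config.frf_path) if config.frf_path \
        else synth.make_fixture_frf_study(config.seed)
    species = sorted(frf["species"].unique())
    gains = _load_gains(config, species)
    curves = tf.emtf_from_frf(frf, gains)
    log.info("emtf arm: %d specimens over %d species", len(curves),
             len(species))

    humans = [c for c in curves if c.species == "Homo sapiens"]
    panins = [c for c in curves if c.species.startswith("Pan ")]
    chimps = [c for c in curves if c.species == "Pan troglodytes"]
    mean_h = tf.group_mean(humans, "mean-human")
    mean_p = tf.group_mean(panins, "mean-panin")
    mean_c = tf.group_mean(chimps, "mean-chimp")
    feats = {"human": tf.extract_features(mean_h),
             "panin": tf.extract_features(mean_p)}
    comp = tf.compare_groups(panins, humans)   # diff = panin - human

    # difference sets against the published candidates
    table = config.audiogram_path or synth.make_fixture_audiograms(config.seed)
    auds = ag.load_audiograms(table)
    hum_aud = next(a for a in auds if a.species == "Homo sapiens"
                   and a.method == "speaker")
    deltas = {}
    for label, variant in (("ELDER", "elder"), ("KOJIMA", "kojima")):
        ch = next(a for a in auds if a.species == "Pan troglodytes"
                  and variant in a.source)
        deltas[label] = dl.build_delta(ch, hum_aud, dl.DELTA_FREQS_HZ[label],
                                       label, orientation="chimp-human")
    deltas["AVERAGE"] = dl.DeltaSet(
        "AVERAGE", deltas["ELDER"].freqs_hz,
        0.5 * (deltas["ELDER"].values_db + deltas["KOJIMA"].values_db),
        orientation="chimp-human")

    d125 = dl.extrapolate_delta_125(mean_h, mean_c)
    emtf_f = np.array(dl.DELTA_FREQS_HZ["EMTF"], dtype=float)
    emtf_vals = np.concatenate(
        [[d125], mean_h.value_at(emtf_f[1:] / 1e3) -
         mean_c.value_at(emtf_f[1:] / 1e3)])
    deltas["EMTF"] = dl.DeltaSet("EMTF", emtf_f, emtf_vals,
                                 orientation="human-chimp")
    power = synth.fixture_power_transmission_deltas()
    deltas["POWER"] = dl.DeltaSet("POWER",
                                  power["frequency_hz"].to_numpy(),
                                  power["delta_db"].to_numpy(),
                                  orientation="human-chimp")

    audiogram_freqs = deltas["ELDER"].freqs_hz
    emtf_on_aud = deltas["EMTF"].restrict(audiogram_freqs)
    fits = [dl.fit_linear(emtf_on_aud, deltas[lab])
            for lab in ("ELDER", "KOJIMA", "AVERAGE")]
    fits.append(dl.fit_linear(deltas["EMTF"].restrict(deltas["POWER"].freqs_hz),
                              deltas["POWER"]))
    fits = dl.adjust_family(fits)
    ratios = dl.evidence_ratios(fits[:3])

    report = {
        "arm": "emtf",
        "provenance": _provenance(config, {"frf": config.frf_path,
                                           "audiograms": config.audiogram_path}),
        "n_specimens": {"human": len(humans), "panin": len(panins)},
        "features": {g: {"extrema": f.extrema,
                         "slopes_db_per_octave": f.slopes}
                     for g, f in feats.items()},
        "comparison": {
            "bands": comp.bands,
            "fraction_significant": comp.fraction_significant,
            "panin_minus_human_mean_db": float(comp.diff.mean()),
        },
        "delta_emtf_125hz_db": d125,
        "regressions": [vars(f) for f in fits],
        "evidence_ratios_vs_best": ratios,
    }
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([
            {"specimen": c.specimen, "species": c.species,
             "frequency_khz": f, "magnitude_db": m}
            for c in curves for f, m in zip(c.grid_khz, c.magnitude_db)
        ]).to_csv(out / "emtf_curves.csv", index=False)
        write_report(report, out / "emtf.json")
    return report


def write_report(report: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    path.write_text(json.dumps(report, indent=2, default=default))
    log.info("wrote %s", path)
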