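"""Generator contracts: determinism, causality, parameter recovery."""
import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from catransient import (PRESETS, ClassifierConfig, ConditionPreset,
                         PresetError, SimConfig, classify_responders,
                         compute_dff, compute_release, auc,
                         percent_responders, simulate_ct_table,
                         simulate_de_tables, simulate_release_traces,
                         simulate_traces, consensus_de, ddct_fold_change)
from catransient.simulate import kernel_peak_time, transient_kernel


def cfg(preset, n_cells=200, seed=7, **kw):
    return SimConfig(n_cells=n_cells, preset=preset, seed=seed, **kw)


def test_same_seed_reproduces_traces_bit_for_bit():
    a = simulate_traces(cfg(PRESETS["eaa-withdrawal"]))
    b = simulate_traces(cfg(PRESETS["eaa-withdrawal"]))
    assert a.traces.F.tobytes() == b.traces.F.tobytes()
    assert a.truth.equals(b.truth)
    assert a.cells.equals(b.cells)
    c = simulate_traces(cfg(PRESETS["eaa-withdrawal"], seed=8))
    assert a.traces.F.tobytes() != c.traces.F.tobytes()


def test_no_evoked_signal_before_stimulus():
    noiseless = dataclasses.replace(PRESETS["control"], noise_sd=0.0)
    ds = simulate_traces(cfg(noiseless, n_cells=50))
    pre = ds.traces.times_s < ds.traces.stim_time_s
    # raw fluorescence is bit-identical to baseline before the stimulus
    assert np.all(ds.traces.F[:, pre] == ds.traces.F[:, [0]])
    dff = compute_dff(ds.traces)
    assert np.abs(dff.dff[:, pre]).max() < 1e-12


def test_kernel_is_causal_unit_peak():
    t = np.linspace(-50, 300, 10000)
    k = transient_kernel(t, 4.0, 30.0)
    assert np.all(k[t <= 0] == 0.0)
    assert k.max() == pytest.approx(1.0, abs=1e-6)
    tpk = kernel_peak_time(4.0, 30.0)
    assert transient_kernel(np.array([tpk]), 4.0, 30.0)[0] == pytest.approx(1.0)


@pytest.mark.parametrize("field,value", [
    ("responder_prob", 1.5),
    ("tau_rise_s", 40.0),       # rise slower than decay
    ("noise_sd", -0.1),
    ("maint_multiplier", -1.0),
])
def test_invalid_preset_rejected_naming_field(field, value):
    preset = dataclasses.replace(PRESETS["control"], **{field: value})
    with pytest.raises(PresetError, match=field.split("_")[0]):
        simulate_traces(cfg(preset))


def test_unseeded_simulation_is_an_error():
    with pytest.raises(PresetError, match="seed"):
        SimConfig(n_cells=10, preset=PRESETS["mock"], seed=None).validate()


def test_responder_prob_extremes_recovered_downstream():
    ds0 = simulate_traces(cfg(PRESETS["mock"], n_cells=200))
    calls0 = classify_responders(compute_dff(ds0.traces))
    assert percent_responders(calls0) == 0.0

    all_resp = dataclasses.replace(PRESETS["control"], name="all")
    ds1 = simulate_traces(cfg(all_resp, n_cells=200, seed=3))
    dff = compute_dff(ds1.traces)
    calls1 = classify_responders(dff)
    # brute-force max over post-stimulus frames, independent of the classifier
    post = dff.times_s >= ds1.traces.stim_time_s
    brute = (dff.dff[:, post].max(axis=1) >= 1.5)
    assert calls1["is_responder"].to_numpy().tolist() == brute.tolist()
    assert percent_responders(calls1) == 100.0


def test_truth_covers_every_cell_and_segment_vocabulary():
    ds = simulate_traces(cfg(PRESETS["arginine-withdrawal"], n_cells=120, seed=5))
    assert sorted(ds.truth["cell_id"]) == sorted(ds.traces.cell_ids)
    assert not ds.truth["cell_id"].duplicated().any()
    assert set(ds.cells["segment"]) <= {"T3", "A1", "A2", "A3", "A4", "A5"}
    assert set(ds.cells["hemisegment"]) <= {"L", "R"}


def test_hemisegment_probability_vector_biases_labels():
    probs = [0.0] * 12
    probs[0] = 1.0  # everything in T3L
    ds = simulate_traces(cfg(PRESETS["mock"], n_cells=50, seed=2,
                             hemisegment_probs=probs))
    assert (ds.cells["segment"] == "T3").all()
    assert (ds.cells["hemisegment"] == "L").all()


def test_maintenance_knockdown_spares_initiation_phase():
    """Zeroing the maintenance event rate leaves 60-300 s AUC unchanged in
    distribution but depresses 300-600 s AUC (the phase dissociation)."""
    n = 200
    base = PRESETS["control"]
    blocked = PRESETS["maintenance-block"]
    d_ctrl = compute_dff(simulate_traces(cfg(base, n_cells=n, seed=11)).traces)
    d_blk = compute_dff(simulate_traces(cfg(blocked, n_cells=n, seed=12)).traces)
    init_c = auc(d_ctrl, (60, 300))["auc"]
    init_b = auc(d_blk, (60, 300))["auc"]
    late_c = auc(d_ctrl, (300, 600))["auc"]
    late_b = auc(d_blk, (300, 600))["auc"]
    t_init = stats.ttest_ind(init_c, init_b)
    assert t_init.pvalue > 0.01
    t_late = stats.ttest_ind(late_c, late_b, alternative="greater")
    assert t_late.pvalue < 0.01


def test_release_traces_monotone_and_asymptote():
    noiseless = dataclasses.replace(PRESETS["mock"], noise_sd=0.0)
    ds = simulate_release_traces(cfg(noiseless, n_cells=20, seed=4),
                                 release_fraction=1.0, drop_magnitude=0.4,
                                 tau_release_s=60.0)
    rel = compute_release(ds.traces)
    post = rel.times_s >= ds.traces.stim_time_s
    diffs = np.diff(rel.dff[:, post], axis=1)
    assert np.all(diffs >= -1e-12)          # monotone fluorescence loss
    expected_end = 0.4 * (1 - math.exp(-(600 - 60) / 60.0))
    assert rel.dff[:, -1] == pytest.approx(expected_end, abs=1e-9)


def test_release_fraction_zero_gives_no_signal():
    ds = simulate_release_traces(cfg(PRESETS["mock"], n_cells=50, seed=6),
                                 release_fraction=0.0, drop_magnitude=0.4)
    rel = compute_release(ds.traces)
    assert np.abs(rel.dff).max() < 0.5      # noise only, far below any drop
    calls = classify_responders(rel, ClassifierConfig(threshold=0.3))
    assert percent_responders(calls) == 0.0


def test_release_fraction_recovered_within_binomial_ci():
    """Classification must agree with the planted releasing set exactly, and
    the exact binomial 95% CI around the classified count must cover the
    nominal fraction at its stated rate (checked over 20 independent draws,
    since any single draw misses with 5% probability by construction)."""
    covered = 0
    for seed in range(20):
        ds = simulate_release_traces(cfg(PRESETS["mock"], n_cells=400, seed=seed),
                                     release_fraction=0.5, drop_magnitude=0.4,
                                     tau_release_s=60.0)
        rel = compute_release(ds.traces)
        calls = classify_responders(rel, ClassifierConfig(threshold=0.3))
        assert calls["is_responder"].tolist() == ds.truth["is_responder"].tolist()
        k = int(calls["is_responder"].sum())
        ci = stats.binomtest(k, 400).proportion_ci(confidence_level=0.95,
                                                   method="exact")
        covered += ci.low <= 0.5 <= ci.high
    assert covered >= 17


def test_drop_magnitude_bounds_enforced():
    c = cfg(PRESETS["mock"], n_cells=5, seed=1)
    with pytest.raises(PresetError, match="drop_magnitude"):
        simulate_release_traces(c, release_fraction=0.5, drop_magnitude=1.0)
    with pytest.raises(PresetError, match="release_fraction"):
        simulate_release_traces(c, release_fraction=1.5, drop_magnitude=0.3)


def test_de_tables_planted_sets_recovered_exactly():
    tables = simulate_de_tables(n_genes=60, n_down=10, n_up=2,
                                fc_down=0.5, fc_up=2.0, seed=21)
    res = consensus_de(tables)
    assert res.down == {f"g{i:04d}" for i in range(10)}
    assert res.up == {"g0010", "g0011"}

    empty = simulate_de_tables(n_genes=30, n_down=0, n_up=0,
                               fc_down=0.5, fc_up=2.0, seed=22)
    res0 = consensus_de(empty)
    assert res0.up == set() and res0.down == set()


def test_de_tables_per_method_miss_shrinks_intersection_by_that_count():
    missed = ["g0000", "g0003", "g0007"]
    tables = simulate_de_tables(n_genes=40, n_down=10, n_up=0, fc_down=0.5,
                                fc_up=2.0, seed=23, miss={"deseq": missed})
    res = consensus_de(tables)
    assert res.down == {f"g{i:04d}" for i in range(10)} - set(missed)


def test_de_tables_inconsistent_counts_rejected():
    with pytest.raises(PresetError):
        simulate_de_tables(n_genes=5, n_down=4, n_up=3, fc_down=0.5,
                           fc_up=2.0, seed=1)
    with pytest.raises(PresetError):
        simulate_de_tables(n_genes=10, n_down=1, n_up=1, fc_down=1.2,
                           fc_up=2.0, seed=1)


def test_ct_table_noiseless_recovery_is_exact():
    ct = simulate_ct_table(["geneA", "geneB"], {"geneA": 0.5, "geneB": 1.0},
                           housekeeping=["rp49"], ct_noise_sd=0.0, seed=31)
    folds = ddct_fold_change(ct, ["geneA", "geneB"], "rp49", "expt", "control")
    by_gene = folds.set_index("gene")["fold_change"]
    assert by_gene["geneA"] == pytest.approx(0.5, abs=1e-12)
    assert by_gene["geneB"] == pytest.approx(1.0, abs=1e-12)


def test_ct_table_noisy_recovery_within_two_sem():
    planted = {"geneA": 0.58, "geneB": 0.42}
    ct = simulate_ct_table(list(planted), planted, housekeeping=["rp49"],
                           ct_noise_sd=0.1, seed=32, n_bio_replicates=100)
    expts = [f"expt_r{i}" for i in range(1, 101)]
    ctrls = [f"control_r{i}" for i in range(1, 101)]
    folds = ddct_fold_change(ct, list(planted), "rp49", expts, ctrls)
    for gene, fold in planted.items():
        vals = folds.loc[folds["gene"] == gene, "fold_change"]
        sem = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - fold) < 2 * sem


def test_ct_table_rejects_bad_folds():
    with pytest.raises(PresetError, match="fold change"):
        simulate_ct_table(["g"], {"g": -1.0}, ["rp49"], 0.0, seed=1)
    with pytest.raises(PresetError, match="housekeeping"):
        simulate_ct_table(["g"], {"g": 0.5, "rp49": 2.0}, ["rp49"], 0.0, seed=1)
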