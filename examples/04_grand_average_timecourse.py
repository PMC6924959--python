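"""Grand-average EPSP time courses per cell type.

Averages baseline-subtracted, peak-normalized mean traces across cells of
each type and compares rise speed: PV cells, with their fast synaptic
kinetics, reach half-maximum earlier than excitatory cells.
"""

import thalamap as tm

cfg = tm.default_config(
    "VPM",
    n_slices=4,
    group_params={
        ("EXC", "L4"): tm.GroupParams(1.0, 0.37, 8),
        ("PV", "L4"): tm.GroupParams(1.15, 0.92, 6),
        ("SST", "L4"): tm.GroupParams(0.09, 0.08, 4),
    },
    trace_len_s=0.24,
    stim_onset_s=0.11,
    seed=1,
)
sweepsets, metas = tm.simulate_dataset(cfg)
tc = tm.build_grand_average_timecourse(sweepsets, metas, normalize_per_cell=True)

for ct in ("EXC", "PV", "SST"):
    sub = tc[tc.cell_type == ct]
    peak = sub.mean_mV.max()
    t_half = sub[(sub.t_ms > 0) & (sub.mean_mV >= 0.5 * peak)].t_ms.iloc[0]
    t_peak = sub.loc[sub.mean_mV.idxmax(), "t_ms"]
    print(
        f"{ct}: half-max at {t_half:5.2f} ms, peak at {t_peak:5.2f} ms "
        f"({int(sub.n_cells.iloc[0])} cells)"
    )
print(
    "\nPV EPSPs rise and peak earliest (tau_rise 0.5 ms vs 2 ms for EXC); "
    "times are ms after the 1 ms light pulse."
)
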