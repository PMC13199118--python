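# Data dictionary

All lengths SI meters, velocities m/s, stresses Pa, times s, unless a
column name says otherwise.

## results/study/metrics.csv — one row per simulated model
| column | meaning |
|---|---|
| group | tortuosity preset: low / medium / high (index 1.05 / 1.15 / 1.30) |
| stenosis | diameter-stenosis fraction of the third segment (0.40–0.70) |
| stented | False = pre-stent (curved, narrowed), True = post-stent (straightened, lumen restored) |
| velocity_minimum / _peak / _intermediate | third-segment area-weighted mean speed at the waveform minimum (t=0), peak (t=T/2), mid-deceleration (t=3T/4) |
| velocity_cycle_avg | Δt-weighted cycle mean of the above |
| wss_minimum / _peak / _intermediate | third-segment, both-wall arc-length-weighted mean \|wss\| at the same phases |
| wss_cycle_avg | cycle mean of the above |

## results/study/reductions.csv — one row per (group, stenosis)
| column | meaning |
|---|---|
| velocity_reduction_pct | 100·(pre − post)/pre of velocity_cycle_avg |
| wss_reduction_pct | same for wss_cycle_avg |

## results/study/variations_stenosis.csv — one row per group
| column | meaning |
|---|---|
| velocity_pp / wss_pp | reduction at s=0.70 minus at s=0.40, percentage points |

## results/study/variations_tortuosity.csv — one row per stenosis level
| column | meaning |
|---|---|
| velocity_pp / wss_pp | max − min reduction across the three groups, percentage points |

## results/geometry/tortuosity_index.csv
| column | meaning |
|---|---|
| tortuosity_four_arc | arc length / chord length over the four-arc region |
| tortuosity_third_segment | same over the third segment only |
| min_half_width_mm | minimum lumen half-width (mm) |
| length_mm | total centerline length (mm) |

## results/geometry/<model>.csv — representative contours
(s, x, y, h, segment) along the centerline plus (x_upper, y_upper,
x_lower, y_lower) wall offsets.

## results/mesh/hardest_cell_transient.csv
Ladder report: rung index, axial_spacing, nj, n_cells, monitor_value
(cycle-averaged third-segment velocity), rel_diff_to_next (the <5%
selection quantity).

## results/mesh/all_geometries_steady.csv
Per study geometry: selected_rung (index into the default 4-rung
ladder), rungs_evaluated (lazy evaluation stops once the rule is met),
rel_diff (relative difference of the selected rung to the next).

## results/acceptance.json
`{"t3"|"t4"|"t6"|"t7": {"value": ..., "n": ...}}` — the headline
quantities recomputed from scratch (see scripts/acceptance.py
docstring); `n` is the number of matrix runs each value draws on.
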