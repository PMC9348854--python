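"""Community turnover along currents: cumulative correlation and e-folding fit.

Generates a small seascape end to end (field -> travel times ->
communities -> Jaccard dissimilarity), then (a) traces the Spearman
correlation between dissimilarity and travel time as a function of a
T_min ceiling, and (b) fits the exponential decay y = C0 exp(-x/tau) of
community similarity against travel time. The fitted tau estimates the
designed turnover time (1 year here): after tau years of transport,
community similarity has decayed by ~63%.
"""

import numpy as np

from seascape import (
    cumulative_correlation,
    jaccard_dissimilarity,
    make_velocity_field,
    place_stations,
    precompute_monthly_tables,
    simulate_communities,
    stitch_all_stations,
    tmin_matrix,
    turnover_fit,
)

field = make_velocity_field(64, 128, 24, seed=11)
stations = place_stations(field, 20, seed=12)
tables = precompute_monthly_tables(field, dt=field.month_length / 300, K=100.0, seed=13)
ens = stitch_all_stations(tables, field, stations, radius_cells=2.0,
                          n_trajectories=100, n_years=20, seed=14)
tsym = tmin_matrix(ens, stations, min_connections=5).symmetrized()

comm = simulate_communities(stations, tsym, tau_true=1.0, n_taxa=2000, seed=15)
D = jaccard_dissimilarity(comm.presence)

thresholds = np.arange(1 / 12, 3.0 + 1e-9, 3 / 12)
curve = cumulative_correlation(D, tsym, thresholds, min_pairs=30)
print("cumulative Spearman correlation vs T_min ceiling:")
print(curve.to_frame()[["t", "rho", "n_pairs"]].round(3).to_string(index=False))

basins = stations["basin"].to_numpy()
same = basins[:, None] == basins[None, :]
iu = np.triu_indices(len(stations), k=1)
w = same[iu]
fit = turnover_fit(100.0 - D.values[iu][w], tsym[iu][w], t_max=1.5)
print(
    f"\nexponential turnover fit on within-basin pairs (T_min < {fit.t_max} y):\n"
    f"  C0 = {fit.c0:.1f} (similarity at zero travel time, percent)\n"
    f"  tau = {fit.tau:.2f} years (designed value: 1.0)\n"
    f"  rms residual = {fit.rms:.1f} on n = {fit.n} station pairs"
)
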