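"""Fit the single-bond model to a mean-force spectrum.

Builds a noiseless spectrum from the closed-form mean rupture force
(equilibrium force 20 pN, x_t = 0.3 nm, k_off = 0.5 /s), perturbs it
slightly, and fits back the three bond parameters — the self-consistency
check at the core of the analysis.
"""
import numpy as np

from polydfs import (
    BondParams,
    MeanForcePoint,
    fit_single_bond_model,
    mean_rupture_force,
    thermal_energy,
)

kBT = thermal_energy()  # 20 C
truth = BondParams(k_off=0.5, x_t=0.3, f_eq=20.0)
rng = np.random.default_rng(0)

points = []
for i, r in enumerate(np.geomspace(0.1, 1e5, 9)):
    f = mean_rupture_force(float(r), truth, kBT) + rng.normal(0.0, 0.3)
    points.append(MeanForcePoint(mean_r=float(r), mean_f=float(f), sem_f=0.3,
                                 n_events=150, velocity=float(i + 1)))

fit = fit_single_bond_model(points, kBT)
p, ci = fit.params, fit.ci95
print("truth : f_eq = 20.00 pN, x_t = 0.300 nm, k_off = 0.500 /s")
print(f"fitted: f_eq = {p.f_eq:.2f} pN (+-{ci.get('f_eq_pN', float('nan')):.2f}), "
      f"x_t = {p.x_t:.3f} nm (+-{ci.get('x_t_nm', float('nan')):.3f}), "
      f"k_off = {p.k_off:.3f} /s (+-{ci.get('k_off_per_s', float('nan')):.3f})")
print("\nThe low-rate points pin the equilibrium plateau f_eq; the slope of")
print("force vs ln(rate) at high rates sets x_t; their junction sets k_off.")
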