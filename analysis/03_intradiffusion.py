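#!/usr/bin/env python
"""Intra-diffusion analysis: Kd and tau per composition, the exponential
tau(x) domain model, and breakpoint segmentation of ln k1.

Findings: Kd rises and tau falls strictly with doping (tau from ~6800 min
at x=0 to ~40 min at x=0.5); ln(tau/tau0) is close to linear within each of
the three composition domains; and the unconstrained 2-breakpoint search on
ln k1 puts the domain edges at 0.15 and 0.35, bracketing the reported
boundaries x = 0.2 and 0.3.  Writes results/intradiffusion.json.
"""

import json

import numpy as np

from photokin import load_fixture
from photokin.diffusion import (
    fit_intradiffusion,
    fit_tau_exponential,
    kd_from_tau,
    segment_domains,
)
from photokin.kinetics import fit_first_order
from photokin.pipeline import _jsonable

series = sorted(load_fixture("table2"), key=lambda s: s.x)
fits = {s.x: fit_intradiffusion(s) for s in series}
print("x      Kd (min^-0.5)   tau (min)   R")
for x, f in fits.items():
    print(f"{x:<6} {f.kd:<15.6f} {f.tau:<11.1f} {f.correlation:.4f}")

model = fit_tau_exponential([(x, f.tau) for x, f in fits.items()])
print(f"\ntau0 = {model.tau0:.1f} min  ->  Kd0 = {kd_from_tau(model.tau0):.6f} min^-0.5")
for seg in model.segments:
    print(f"domain [{seg.x_lo}, {seg.x_hi}]: theta = {seg.theta:.2f}, "
          f"x0 = {seg.x0:.4f}, R = {seg.correlation:.4f}")

lnk = [(s.x, float(np.log(fit_first_order(s).k1))) for s in series]
seg = segment_domains(lnk, n_breakpoints=2)
print(f"\nln k1 breakpoints (exhaustive search): {seg.breakpoints}")

payload = {
    "per_x": {str(x): {"kd": f.kd, "tau": f.tau, "correlation": f.correlation}
              for x, f in fits.items()},
    "tau_model": {
        "tau0": model.tau0,
        "kd0": kd_from_tau(model.tau0),
        "segments": [vars(s) for s in model.segments],
    },
    "lnk1_breakpoints": list(seg.breakpoints),
}
with open("results/intradiffusion.json", "w") as fh:
    json.dump(_jsonable(payload), fh, indent=2)
    fh.write("\n")
print("wrote results/intradiffusion.json")
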