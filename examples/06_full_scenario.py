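"""End-to-end stimulation-scenario analysis on the default phantom.

Runs the full modular workflow (anatomy -> orientation fields -> fibers ->
electrodes -> unit potentials -> thresholds -> selectivity) for the
monopolar and transverse-parallel electrode configurations at the target
ampulla.  Takes a couple of minutes on one core.
"""

import logging

from vestim.pipeline import ScenarioConfig, run_scenario

logging.basicConfig(level=logging.INFO)

config = ScenarioConfig(
    fibers_per_branch=20,
    seed=1,
    configurations=["monopolar", "transverse_parallel"],
    out_dir="scenario_out",
)
result = run_scenario(config)

print(f"{'configuration':24s} {'AUC':>6s} {'80% amplitude':>14s} {'R_access':>9s}")
for name, rep in result.reports.items():
    print(f"{name:24s} {rep.auc:6.3f} {rep.amplitude_80pct * 1e3:11.2f} mA "
          f"{rep.access_resistance_ohm:7.1f} Ohm")
print("-> the monopolar electrode couples strongly (low amplitude) but "
      "recruits the neighbor branch almost alongside the target (low AUC); "
      "the transverse-parallel dipole needs more current but is selective.")
print("artifacts (mesh, fibers, thresholds, reports) in scenario_out/")
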