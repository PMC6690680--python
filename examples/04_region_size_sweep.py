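"""Sweep the size of the central ischemic region on one fiber.

Places mild and severe ischemic regions of 0.5-2 cm (with 0.1 cm linear
transition zones) at the middle of the fiber and tracks two contrasting
biomarkers: the QT interval falls monotonically with region size (it is
set by the depolarization path), while the ST deviation peaks at
intermediate sizes, where repolarization along the fiber is most
dyssynchronous.
"""

from epom import IschemiaSpec, PacingProtocol, ParameterSet, steady_state
from epom.pipeline import RunConfig, region_size_sweep

baseline = ParameterSet.baseline()
config = RunConfig(warm_start=True, cable_beats=3, cable_dt=0.05)
warm = steady_state(baseline, IschemiaSpec.control(),
                    PacingProtocol(cl=600.0, n_beats=200), dt=0.1)

sweep = region_size_sweep(baseline, config, zones=(0.5, 1.0, 1.5, 2.0),
                          control_state=warm)

for sev in ("mild", "severe"):
    sub = sweep[sweep["severity"] == sev].sort_values("zone_size")
    print(f"\n{sev} ischemic region:")
    print(f"  {'zone (cm)':>9} {'QT (ms)':>8} {'ST dev':>8} {'T amp':>8}")
    for _, row in sub.iterrows():
        print(f"  {row.zone_size:9.1f} {row.qt_interval:8.1f} "
              f"{row.st_deviation:8.3f} {row.t_amplitude:8.2f}")

print("\nQT falls monotonically with zone size; |ST| and |T amplitude| "
      "peak at intermediate sizes (the repolarization-dyssynchrony effect).")
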