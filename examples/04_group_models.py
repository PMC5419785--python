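"""Per cultivar-type and yield-level models from a synthetic experiment.

Generates the default factorial design (2 cultivars x 6 N rates x 3
replicates) in memory, normalizes each cultivar-type x yield-level
group, fits a double logistic per group, and compares the high-yield
Indica vs Japonica parameters with a Wald z-test.
"""

import warnings

from rndvi import (
    accumulate,
    build_group_dataset,
    compare_parameters,
    default_design,
    fit_group_models,
    gen_experiment,
)
from rndvi.types import CultivarType, YieldLevel

weather, plots, series_list = gen_experiment(default_design(seed=3))
thermal = {s.plot.plot_id: accumulate(weather, s.plot) for s in series_list}

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    datasets = build_group_dataset(series_list, thermal)
    fits = fit_group_models(datasets)

print(f"{'group':18s} {'a':>8s} {'b':>7s} {'c':>8s} {'d':>7s} {'R^2':>7s} {'n':>4s}")
for (ctype, level), fit in sorted(fits.items(), key=lambda kv: repr(kv[0])):
    a, b, c, d = fit.spec.params
    label = f"{ctype.value}/{level.value}"
    print(
        f"{label:18s} {a:8.3f} {b:7.3f} {c:8.3f} {d:7.3f}"
        f" {fit.r2:7.4f} {fit.n:4d}"
    )

indica = fits[(CultivarType.INDICA, YieldLevel.HIGH)]
japonica = fits[(CultivarType.JAPONICA, YieldLevel.HIGH)]
print("\nHigh-yield Indica vs Japonica parameter comparison (Wald z):")
for name, (z, p) in compare_parameters(indica, japonica).items():
    print(f"  {name}: z = {z:7.2f}, p = {p:.3g}")
print(
    "\nIndica green-up is steeper and earlier (larger a, smaller b) - its"
    "\nloose leaf morphology closes the canopy faster; senescence timing"
    "\n(d) is similar for both types."
)
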