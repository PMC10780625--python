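"""Classify planted spatial structure with Ripley's K and Monte Carlo envelopes.

Builds a clustered (Thomas) and an inhibited (hardcore) pattern in a 40 m
circular plot, runs the univariate L(d) test against 99 CSR simulations,
then tests two mutually repelled groups with the bivariate L12(d) against
the rotation null.  Prints the per-distance classifications: the envelope
labels distances where the observed statistic leaves the 95% band.
"""

from dendrostand import bivariate_null_envelope, csr_envelope
from dendrostand.synthetic import (
    Hardcore,
    Poisson,
    Repulsion,
    SpatialScenario,
    ThomasCluster,
    generate_point_pattern,
)


def show(name, res, upto=10):
    labels = ", ".join(f"{int(d)}m:{c}" for d, c in zip(res.distances[:upto], res.classification[:upto]))
    print(f"{name}\n  {labels}")


clustered = generate_point_pattern(SpatialScenario(
    n_per_class={"A": 100},
    process_per_class={"A": ThomasCluster(parent_intensity=4e-4, cluster_sd=2.0)},
    seed=0))
show("Thomas cluster pattern (expect 'clustered' at a few metres):",
     csr_envelope(clustered, d_max=10, seed=1))

inhibited = generate_point_pattern(SpatialScenario(
    n_per_class={"A": 60}, process_per_class={"A": Hardcore(6.0)}, seed=0))
show("Hardcore pattern, min distance 6 m (expect 'regular' below 6 m):",
     csr_envelope(inhibited, d_max=10, seed=2))

segregated = generate_point_pattern(SpatialScenario(
    n_per_class={"A": 40, "B": 40},
    process_per_class={"A": Poisson(), "B": Poisson()},
    cross_class_rule=Repulsion(8.0), seed=0))
show("Two groups kept >= 8 m apart (expect 'repulsion' below 8 m):",
     bivariate_null_envelope(segregated, "A", "B", d_max=10, seed=3))
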