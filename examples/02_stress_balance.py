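"""Recover the active/viscous stress balance from an extensional flow.

The fixture plants an extension rate E = 0.56 (bundles elongate along the
director at constant rate).  Discovery on the scalar library returns
Qbar:Abar + c5' = 0; the symmetric-traceless library returns the two-term
tensor balance (Abar:Qbar) Qbar + c5 Qbar = 0.  Both coefficients equal -E
once the nondimensionalization time scale is undone.
"""

from spider2d import field_data, pipeline
from spider2d.sparse_regression import DiscoveryConfig, discover_all
from spider2d.synthetic_fields import make_fixture
from spider2d.term_library import fingerprint_dedup, generate_library
from spider2d.weak_form import WeakFormConfig, build_feature_matrix

fields, truth = make_fixture("eq9", seed=1)
print(f"planted extension rate E = {truth['extension_rate']}")
nondim, scales = field_data.nondimensionalize(fields)
probes = pipeline.default_probes(3)

library = generate_library(pipeline.LIBRARY_SPECS["scalar_even"]())
library = fingerprint_dedup(library, probes, seed=5)
fm = build_feature_matrix(library, nondim, config=WeakFormConfig(seed=11))
report = discover_all(library, fm.G, fm.xi, DiscoveryConfig(seed=2))
rel, c5p = pipeline.extract_scalar_balance(report)
print(f"scalar balance: {rel.pretty}")
print(f"  c5' = {c5p / scales.time:+.4f} in fixture units (expected {truth['c5']:+.4f})")
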