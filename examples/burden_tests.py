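"""The case-control rare-variant burden tests on the bundled variant table.

Reproduces the study's carrier-level and variant-level one-tailed Fisher
exact tests: 278 SIDS cases vs 729 controls, variants qualifying at ExAC
allele frequency < 5e-5 or novel.
"""

from navclamp.burden import carrier_burden, variant_level_burden
from navclamp.reference_data import (N_CASES, N_CASES_US, N_CONTROLS,
                                     variant_records)

records = variant_records()

for label, kwargs in [
        ("all rare carriers", dict(selector="all")),
        ("functionally disruptive carriers", dict(selector="functional")),
        ("functional carriers, US cohort only",
         dict(selector="functional", subcohort="US")),
        ("functional carriers, intronic counted deleterious",
         dict(selector="sensitivity"))]:
    n_cases = N_CASES_US if kwargs.get("subcohort") == "US" else N_CASES
    res = carrier_burden(records, n_cases, N_CONTROLS, **kwargs)
    t = res.table
    print(f"{label:50s} {t.a}/{t.n_cases} vs {t.b}/{t.n_controls}  "
          f"p = {res.p_display}")

res = variant_level_burden(records)
t = res.table
print(f"{'disruptive variants (variant-level)':50s} "
      f"{t.a}/{t.n_cases} vs {t.b}/{t.n_controls}  p = {res.p_display}")

print("\nOnly the tests restricted to functionally disruptive variants reach "
      "significance: rare SCN4A variants as such are not enriched in cases "
      "(p=0.21), but functionally disruptive ones are (p=0.0057).")
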