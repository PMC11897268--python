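"""Alternative-scenario sensitivity analyses.

Re-evaluates each analysis after (i) swapping linezolid for vancomycin in
both treatment lines, (ii) making cefiderocol the single second-line option,
and (iii) using the lengths of stay observed with beta-lactam antibiotics.
The question is whether any substitution flips the direction of the result
(it does not: extra expenditure in analysis 1, savings in analyses 2 and 3).
"""

from tdmcost import default_schedule, incremental_cost, load_fixture
from tdmcost.parameters import VARIANTS

schedule = default_schedule()
print(f"{'variant':<18}" + "".join(f"  analysis {a:<3}" for a in (1, 2, 3)))
for variant in VARIANTS:
    cells = []
    for analysis in (1, 2, 3):
        inc = incremental_cost(load_fixture(analysis, variant), schedule)
        cells.append(f"{inc:>+11,.0f}€")
    print(f"{variant:<18}" + " ".join(cells))
print("\nIncremental cost per patient, with TDM minus without; "
      "negative values are savings.")
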