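"""Compare measured and simulated fingertip forces with the packaged reference tables.

Computes per-condition differences (simulated - measured) and the accuracy (mean difference)
and precision (sample SD of differences) per force component, reproducing the reference
experiment's summary statistics.
"""

from precigrip import comparison_report, packaged_table

measured = packaged_table("table2_measured")
simulated = packaged_table("table2_simulated")
printed_deltas = packaged_table("table2_deltas")

report = comparison_report(measured, simulated, use_deltas=printed_deltas)
print("accuracy = mean(simulated - measured); precision = sample SD of the differences\n")
print(report["summary"].to_string(index=False, float_format=lambda v: f"{v: .4f}"))
print("\nF_i = vertical load, F_j = transverse, F_k = grip (normal) force [N]; "
      "M_k = torsion about the contact normal [N m], all in object coordinates.")
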