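"""Four disproportionality statistics on a single fourfold table.

Builds the 2x2 table for a hypothetical drug-event pair and prints ROR,
PRR, the BCPNN information component and the simplified EBGM with their
interval bounds and signal flags.
"""

import faerspv as f

# a = target drug with the event, b = target drug other events,
# c = other drugs with the event, d = other drugs other events
table = f.ContingencyTable(a=118, b=11_115, c=350, d=1_100_000)
m = f.compute_metrics(table)

print(f"fourfold table: a={table.a} b={table.b} c={table.c} d={table.d} (N={table.N})")
print(f"ROR  = {m.ror:8.2f}  95% CI ({m.ror_ci_low:.2f}-{m.ror_ci_high:.2f})")
print(f"PRR  = {m.prr:8.2f}  chi2 {m.chi2:.1f}")
print(f"IC   = {m.ic:8.2f}  IC025 {m.ic025:.2f}")
print(f"EBGM = {m.ebgm:8.2f}  EBGM05 {m.ebgm05:.2f}")
print(f"2^IC = {2**m.ic:8.2f}  (identical to EBGM: same quantity, log2 vs linear scale)")
print(
    "signal flags:",
    f"ROR={m.ror_sig} PRR={m.prr_sig} BCPNN={m.bcpnn_sig} MGPS={m.mgps_sig}",
    f"-> all four: {m.all_four}",
)
# A pair is called a signal here only when all four criteria agree:
# ROR CI lower bound > 1 with a >= 3; PRR > 2 with chi2 > 4 and a > 3;
# IC025 > 0; EBGM05 > 2.
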