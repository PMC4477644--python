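"""Why tandem-repeat reads need expanded alignment.

Simulates reads from a 40-mer template whose middle 20 nt are fixed and
whose flanks are random (the classic spike-in for this library design), and
scores the positions-11-30 core criterion with and without rotation
correction. Direct alignment only works when the random rotation phase
happens to be 0 (expected 1/40 = 2.5% of reads); the expanded approach
recovers essentially all reads.
"""

from rollseq import randomized_template_experiment

res = randomized_template_experiment(n=2000, seed=1, per_base_error=0.005)
print(f"reads simulated:            {res['n']}")
print(f"units extracted:            {res['n_extracted']}")
print(f"expanded (rotation-corrected) core recovery: {res['pct_expanded']:.2f}%")
print(f"direct (no deconvolution)   core recovery:   {res['pct_direct']:.2f}%")
print("\nThe direct percentage sits near the analytic 2.5% phase-0 chance;")
print("the expanded percentage shows the deconvolution recovers the template.")
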