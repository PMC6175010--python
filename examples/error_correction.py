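"""Indel error correction inside a repeat tract, before and after.

A repeat unit carrying one indel, flanked by at least two intact units on
each side, is restored to an exact copy.  The example shows the canonical
single-deletion case and the effect on a whole simulated sample: after
correction the number of windows that match no repeat unit ("gray"
interruptions in a repeat-content plot) drops sharply.
"""

from repeatgate import (Rejection, SimulationSpec, classify_read,
                        correct_indels, decompose, extract_repeat,
                        get_design, simulate_sample)

print("single tract:", "CAGCAGCGCAGCAG", "->",
      correct_indels("CAGCAGCGCAGCAG", "CAG"))

htt = get_design("HTT")
spec = SimulationSpec(design=htt, genotype={"CAG": (21, 29), "CCG": (7, 7)},
                      n_reads=200, error_rates=(0.0, 0.005, 0.005), seed=4)
reads, _ = simulate_sample(spec)

pre = post = n_on = 0
for read in reads:
    out = classify_read(read, htt)
    if isinstance(out, Rejection):
        continue
    n_on += 1
    tract = extract_repeat(out)
    fixed = tract
    for unit in htt.units:
        fixed = correct_indels(fixed, unit)
    pre += decompose(tract, htt).n_other
    post += decompose(fixed, htt).n_other

# the CAACAGCCGCCA junction contributes two genuine non-repeat windows per
# read; everything beyond that baseline is sequencing-error artifact
baseline = 2 * n_on
print(f"error-artifact interruption windows: {pre - baseline} before "
      f"correction, {post - baseline} after ({n_on} reads)")
print("-> correction removes most single-base indel artifacts while leaving "
      "anything it cannot attribute to one indel untouched")
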