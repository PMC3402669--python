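"""Pairwise divergence of coding mtDNA with bootstrap standard errors.

Simulates the study-like dataset, strips the hypervariable D-loop in the
reference coordinate frame, and prints substitution-only p-distances
(the familiar "percent divergence"), Tamura-Nei gamma distances (shape
0.1, as used for the study's distance matrices) and 1,000-replicate
bootstrap standard errors.
"""

from bovimito import (bootstrap_se, extract_coding_alignment, p_distance,
                      simulate, study_emulator, tn93_gamma_distance)

genomes, alignment, _ = simulate(study_emulator(seed=1))
coding = extract_coding_alignment(alignment, {g.id: g for g in genomes})
print(f"coding alignment: {coding.length} columns "
      f"(full molecule: {alignment.length})\n")

pairs = [("wisent", "BRS"), ("bison", "BRS"), ("yak", "BRS"),
         ("wisent", "bison"), ("bison", "yak")]
print(f"{'pair':16s} {'p-dist %':>9s} {'TN93+G(0.1)':>12s} {'boot SE':>9s}")
for a, b in pairs:
    p = p_distance(coding, a, b)
    tn = tn93_gamma_distance(coding, a, b, shape=0.1)
    se = bootstrap_se(coding, a, b, p_distance, replicates=1000, seed=7)
    print(f"{a + '-' + b:16s} {100 * p.p_distance:9.2f} "
          f"{tn.tn93_gamma:12.4f} {100 * se:9.3f}")
print("\np-distance counts differing sites only; the gamma-corrected "
      "Tamura-Nei\nvalue adds back multiple hits, strongly so at shape 0.1.")
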