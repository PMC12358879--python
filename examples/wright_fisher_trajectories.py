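"""Wright-Fisher allele-frequency paths under positive selection.

Simulates the rise of a beneficial allele (genotype fitnesses
1, 1+s, 1+2s) and checks the simulator's fixation probability of a
new mutant against Kimura's diffusion approximation.
"""

from adslkit.popgen import (
    diffusion_fixation_probability,
    wf_fixation_probability,
    wright_fisher_trajectory,
)

N, s = 1000, 0.01
traj = wright_fisher_trajectory(N, s, p0=0.02, T=2000, seed=5)
marks = {0: traj.freqs[0], 500: traj.freqs[500], 1000: traj.freqs[1000], 2000: traj.freqs[-1]}
print(f"one trajectory (N = {N}, s = {s}), frequency at selected generations:")
for g, f in marks.items():
    print(f"  generation {g:>4}: {f:.3f}")
print(f"  outcome: {traj.outcome}")

p0 = 1 / (2 * N)
sim = wf_fixation_probability(N, s, p0, replicates=20_000, seed=5)
diff = diffusion_fixation_probability(N, s, p0)
print(
    f"\nfixation probability of a new mutant: simulated {sim:.4f} vs "
    f"diffusion closed form {diff:.4f}"
)
print(
    "\nMost new beneficial mutants are lost to drift; the ~2% that escape "
    "rise in an S-shaped path to fixation, the dynamic behind a selective sweep."
)
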