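"""Closed-form threshold predictions on scale-free networks.

Builds configuration-model scale-free networks with the two degree-cutoff
conventions and compares every closed-form prediction.  With the
structural cutoff (k_max ~ sqrt(N)) degree correlations vanish; with the
natural cutoff (k_max ~ N^{1/(gamma-1)}) and gamma < 3 the network becomes
disassortative, which is the regime where the degree-based (HMF) and
spectral (QMF) predictions separate.
"""

import epithresh as et

for gamma, cutoff in [(2.5, "structural"), (2.25, "natural"), (3.5, "natural")]:
    cfg = et.SFNConfig(n_nodes=10_000, gamma=gamma, cutoff_mode=cutoff)
    net = et.generate_sfn(cfg, rng_seed=1)
    stats = et.degree_stats(net)
    thr = et.compute_thresholds(net, mu=1.0, stats=stats)
    print(f"gamma = {gamma}, {cutoff} cutoff (cap {cfg.degree_cap}):")
    print(f"  <k> = {stats.mean_k:.2f}  <k^2> = {stats.mean_k2:.1f}  "
          f"k_max = {stats.k_max}  r = {stats.assortativity_r:+.3f}")
    print(f"  HMF(SIR) = {thr.hmf_sir:.4f}   QMF = {thr.qmf:.4f}   "
          f"percolation = {thr.percolation:.4f}")
    print()

print("r near 0 under the structural cutoff; r < 0 (disassortative) under")
print("the natural cutoff with gamma < 3.  The heavier the tail, the lower")
print("every threshold; HMF and QMF disagree most on disassortative graphs.")
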