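"""Generate a synthetic paired two-disease study and inspect its ground truth.

The generator plants k=3 patient clusters per disease, each with an up- and
a down-regulated gene module (+/-2 log2 units over baseline, noise sd 0.5),
and a set of 20 candidate genes shared with identical direction between
cluster 3 of both diseases.
"""

from comosub import SimulationDesign, generate_paired_study

study = generate_paired_study(SimulationDesign(seed=1), SimulationDesign(seed=2))

for tag, ds, truth in (
    ("A", study.dataset_a, study.truth_a),
    ("B", study.dataset_b, study.truth_b),
):
    n_pat = int(ds.patient_mask.sum())
    print(f"disease {tag}: {ds.n_genes} genes x {ds.n_samples} samples "
          f"({n_pat} patients, {ds.n_samples - n_pat} controls)")
    sizes = {c: sum(1 for v in truth.sample_cluster.values() if v == c) for c in (1, 2, 3)}
    print(f"  planted cluster sizes: {sizes}")
    print(f"  module sizes: up={len(truth.up_modules[1])}, down={len(truth.down_modules[1])}")

print(f"pathway collection: {len(study.gene_sets)} sets, "
      f"universe {len(study.gene_sets.universe)} genes")
print(f"shared candidates: {len(study.shared_candidates)} genes, e.g. "
      f"{sorted(study.shared_candidates.items())[:3]}")
# each tuple is (gene, planted direction); the same genes are planted in the
# shared cluster pair of BOTH diseases, which the pipeline must rediscover
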