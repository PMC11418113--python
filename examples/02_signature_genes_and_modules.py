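"""Derive subtype signature genes and select subtype-specific modules.

For each subtype, TT genes are upregulated versus the other subtypes and TN
genes versus normal samples (logFC > 1, FDR < 0.05). The final signature is
the intersection of TT, TN and the top genes by two cancer-compartment
fold-change rankings. Candidate coexpression modules are then screened by
hypergeometric overlap with the TT and TN sets.
"""

from ocsubtypes import (BulkSimConfig, ModuleSet, f_scores, generate_bulk,
                        infer_compartments, select_ssmodules,
                        subtype_signatures, tt_tn_sets)

config = BulkSimConfig(effect_size=3.0, seed=30)
matrix, truth = generate_bulk(config)
labels = truth["true_subtype"]
tumors = matrix.subset_samples(matrix.tumor_samples())

# TT/TN differential gene sets per subtype
sets = tt_tn_sets(matrix, labels, list(matrix.normal_samples()))
for s, (tt, tn) in sets.items():
    print(f"{s}: {len(tt)} TT genes, {len(tn)} TN genes")

# F-scores rank genes by across-subtype separation
F = f_scores(tumors, labels)
print("top 5 F-score genes:", list(F.sort_values(ascending=False).index[:5]))

# four-set intersection signatures (cancer-compartment rankings need the
# deconvolved profiles)
profiles = infer_compartments(tumors, labels)
normal_mean = matrix.values[matrix.normal_samples()].mean(axis=1)
sigs = subtype_signatures(sets, {s: p.e_cancer for s, p in profiles.items()},
                          normal_mean, top_n=60)
for s, sig in sigs.items():
    planted = set(truth["signature_genes"][s])
    overlap = len(set(sig.genes) & planted)
    print(f"{s}: {len(sig.genes)}-gene signature, "
          f"{overlap}/{len(planted)} planted genes recovered")

# module screening: one module built from C1's planted genes, one random
universe = set(matrix.genes)
c1 = set(truth["signature_genes"]["C1"])
modules = ModuleSet(
    modules={
        "M1": c1,
        "M1_parent": c1 | set(sorted(universe - c1)[:20]),
        "M_noise": set(sorted(universe)[-15:]),  # background genes
    },
    universe=universe,
    parents={"M1": "M1_parent"},  # M1 nests inside M1_parent
)
table = select_ssmodules(modules, *sets["C1"])
print(table)
print("selected:", list(table.index[table["selected"]]))
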