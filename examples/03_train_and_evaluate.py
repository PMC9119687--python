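"""Train the attention GNN on a small planted-signal benchmark.

Holds out one tissue, trains on the rest and reports threshold metrics and
the area under the ROC curve on the unseen tissue.  Smaller than the full
benchmark so it finishes in about a minute.
"""

from drugraph import GNNConfig, SimConfig, compute_metrics, generate_dataset, train_model

config = SimConfig(n_cell_lines=24, n_tissues=4, n_drugs=8)
graphs, _ = generate_dataset(config, seed=3)
held_out = sorted({g.tissue for g in graphs})[0]
train = [g for g in graphs if g.tissue != held_out]
val = [g for g in graphs if g.tissue == held_out]
print(f"{len(train)} training / {len(val)} validation graphs "
      f"(held-out tissue: {held_out})")

model, log = train_model(train, GNNConfig(seed=1, epochs=40), val_instances=val)
print(f"final training loss {log.final_loss:.3f}")

report = compute_metrics([g.label for g in val], model.predict_proba(val))
print(f"held-out tissue AUC {report.auc:.3f}, "
      f"balanced accuracy {report.balanced_accuracy:.3f}, "
      f"precision {report.precision:.3f}, recall {report.recall:.3f}, "
      f"F {report.f_measure:.3f}")
# An AUC well above 0.5 on a tissue never seen in training means the model
# recovered the planted mechanism (inhibited, up-regulated, disease-associated
# kinases drive cytotoxicity) rather than memorizing cell lines.
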