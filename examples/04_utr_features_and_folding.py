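"""Scan a 5'-UTR for upstream start codons and fold it.

A uORF here is a near-cognate start codon (AUG/CUG/GUG/UUG/ACG) with a
purine at -3 and G at +4; the folding energy is the minimum pair-energy
structure under the package's simple GC/AU/GU model (model units, for
within-run comparisons only).
"""

from translatomics import TranscriptRecord, compute_features, mfe_fold

# 40-nt UTR with one planted AUG in perfect context at position 10,
# followed by the main ORF
utr = "AAAAAAGCCAUGGCCAAAGGGAAACCCAAAAAAAAAAAAA"
transcript = TranscriptRecord("tx1", "prot1", utr + "AUGGCCUAA", cds_start=41)

features = compute_features(transcript, fold_model=mfe_fold)
print(f"UTR length: {features.length} nt   GC: {features.gc_percent:.1f}%")
print(f"uORF starts (1-based): {features.uorf_positions} "
      f"-> count {features.uorf_count}")
print(f"folding delta-G: {features.delta_g:.1f} (model units; "
      "more negative = more structured)")

fold = mfe_fold(utr)
print(f"structure: {fold.structure}")
# The GGGAAACCC stem-loop inside the UTR folds into three GC pairs (-9).
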