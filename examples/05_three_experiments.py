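"""The full three-experiment comparison: cyclic, dihedral, synthetic patches.

Runs simulate -> learn -> wire -> evaluate for the three presets and prints
the comparison summary: intra/inter distance separation on the full grid,
the intra/inter overlap under 10 random thresholds, and the similarity-vs-
threshold-count trend.  Takes a few seconds.
"""

import orbipool as op

result = op.figure1(seed=1)

print(f"{'experiment':<10} {'intra max':>9} {'inter min':>9} "
      f"{'overlap@10':>10} {'trend rho':>9} {'plateau':>8}")
for kind, s in result["summary"].items():
    print(f"{kind:<10} {s['intra_max_full_grid']:>9.1f} "
          f"{s['inter_min_full_grid']:>9.1f} "
          f"{s['overlap_random_thresholds']:>10.3f} "
          f"{s['cosine_trend_spearman']:>9.2f} "
          f"{s['cosine_plateau_gap']:>8.4f}")

print("""
Reading the table:
 - intra max / inter min: l1 signature distances on the full threshold grid;
   for the toy groups every same-orbit distance is exactly 0, strictly below
   the smallest cross-orbit distance (invariant AND selective code);
 - overlap@10: histogram overlap of log intra vs inter distances under the
   10-random-threshold protocol; the rasterized-patch stand-in mixes the two
   distributions more than either toy group, because interpolated rotation
   only approximately satisfies the orthogonal-group assumption;
 - trend rho / plateau: the mean cosine similarity between cross-orbit
   signatures rises with the threshold count (positive Spearman rho) and
   levels off (gap over the last doubling well under 0.02).""")
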