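# Family composition and recorded summary vectors for the two packaged
# arrhythmia-gene fixtures.
#
# Protein lengths for the query genes (RYR2 4967, SCN5A 2016) are those of
# the canonical transcripts listed; other member lengths are canonical
# UniProt lengths and serve only to size the synthetic scaffold alignments.
#
# "recorded" vectors are full-protein summary counts that cannot be
# recomputed from the printed per-variant rows (they derive from a
# proprietary full evidence set); status/observed vectors are ordered
# (pathogenic, benign, uncertain, unannotated).
# Comparator tools evaluated on the same known RYR2+SCN5A missense variants:
# predicted-deleterious counts split into true (unambiguously pathogenic)
# and false (benign) positives.
comparators:
  SIFT: {true_positives: 500, false_positives: 19}
  Polyphen: {true_positives: 497, false_positives: 21}
RYR:
  query: RYR2
  regions: regions_ryr2.tsv
  novel_variants: ryr2_novel_variants.tsv
  members:
    RYR2:
      length: 4967
      transcripts: [NM_001035, NP_001026, ENST00000366574, ENSP00000355533, LRG_402t1]
    RYR1:
      length: 5038
    RYR3:
      length: 4870
  recorded:
    status_counts: [139, 20, 71, 4737]
    observed: [35, 1, 1, 238]
    region_counts:
      hotspots: 157
      outside: 118
    region_known_pathogenic:
      hotspots: 134
      outside: 20
  cohort:
    novel_missense: 31
    annotated: 10
SCN:
  query: SCN5A
  regions: regions_scn5a.tsv
  novel_variants: scn5a_novel_variants.tsv
  paralogue_summary: scn5a_paralogues.tsv
  members:
    SCN5A:
      length: 2016
      transcripts: [NM_198056, NP_932173, ENST00000333535, ENSP00000328968, LRG_289t1]
    SCN1A: {length: 2009}
    SCN2A: {length: 2005}
    SCN3A: {length: 2000}
    SCN4A: {length: 1836}
    SCN7A: {length: 1682}
    SCN8A: {length: 1980}
    SCN9A: {length: 1977}
    SCN10A: {length: 1956}
    SCN11A: {length: 1791}
    CACNA1A: {length: 2506}
    CACNA1B: {length: 2339}
    CACNA1C: {length: 2221}
    CACNA1D: {length: 2181}
    CACNA1E: {length: 2313}
    CACNA1F: {length: 1977}
    CACNA1G: {length: 2377}
    CACNA1H: {length: 2353}
    CACNA1I: {length: 2223}
    CACNA1S: {length: 1873}
  recorded:
    status_counts: [368, 28, 60, 1560]
    observed: [113, 1, 6, 321]
    region_counts:
      transmembrane: 355
      n_terminus: 14
      interlinker: 41
      c_terminus: 31
    region_known_pathogenic:
      transmembrane: 277
      n_terminus: 27
      interlinker: 99
      c_terminus: 40
  cohort:
    novel_missense: 122
    annotated: 45
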