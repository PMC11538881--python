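# Miettinen-Lasota (AFIP) risk classification for GIST, encoded as data so
# that alternative classifications can be dropped in.  Size bands are closed
# on the upper edge (<=2, >2-5, >5-10, >10 cm); the mitotic threshold is 5
# per 5 mm2 (<=5 vs >5).  Cells the original series could not classify are
# kept as insufficient_data rather than coerced to a neighboring class.
name: miettinen-lasota
size_band_edges_cm: [2.0, 5.0, 10.0]
mitotic_threshold_per_5mm2: 5.0
# model site -> classification column; the classification has no colon
# column, so colon-rectum tumors use the rectum column, and small-intestine
# tumors the jejunum/ileum column (both remappable here).
site_groups:
  stomach: stomach
  duodenum: duodenum
  small-intestine: jejunum-ileum
  colon-rectum: rectum
# rows: size band (<=2, >2-5, >5-10, >10 cm); columns: mitoses <=5, >5
classes:
  stomach:
    "<=2": {"<=5": none, ">5": none}
    ">2-5": {"<=5": very_low, ">5": moderate}
    ">5-10": {"<=5": low, ">5": high}
    ">10": {"<=5": moderate, ">5": high}
  duodenum:
    "<=2": {"<=5": none, ">5": insufficient_data}
    ">2-5": {"<=5": low, ">5": high}
    ">5-10": {"<=5": insufficient_data, ">5": insufficient_data}
    ">10": {"<=5": high, ">5": high}
  jejunum-ileum:
    "<=2": {"<=5": none, ">5": high}
    ">2-5": {"<=5": low, ">5": high}
    ">5-10": {"<=5": moderate, ">5": high}
    ">10": {"<=5": high, ">5": high}
  rectum:
    "<=2": {"<=5": none, ">5": high}
    ">2-5": {"<=5": low, ">5": high}
    ">5-10": {"<=5": insufficient_data, ">5": high}
    ">10": {"<=5": high, ">5": high}
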