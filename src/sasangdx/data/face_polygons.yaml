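# Polygon definitions for named area features.  The source vocabulary
# names FArea02 / FArea03 without printing their point lists, so these
# defaults are lower-face contour polygons over frontal outline points;
# override with your own file if your landmark scheme differs.
# view: frontal | profile; points: ordered landmark ids (shoelace area).
FArea02:
  view: frontal
  points: [33, 43, 94, 50, 194, 143, 133]
FArea03:
  view: frontal
  points: [53, 43, 50, 143, 153]
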