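"""Recompute the published evaluation tables from their raw counts.

The package ships the published sex-stratified confusion matrices of
the integrated diagnostic model as plain counts; this example re-derives
every sensitivity and accuracy cell (half-up, one decimal) and prints
the held-out (test) tables before and after the typicality cutoff.
"""

from sasangdx.evaluation import ConfusionSummary, format_report, reference_results

ref = reference_results()
for tag, group in (("integrated model", "proposed"),
                   ("after typicality cutoff", "cutoff")):
    for sex in ("male", "female"):
        entry = ref[group][sex]["test"]
        conf = ConfusionSummary.from_matrix(entry["matrix"], sex=sex,
                                            subset=f"{tag}, test set")
        print(format_report(conf))
        print()

totals = ref["common_samples"]
print(f"common samples across the four modalities: {totals['total']} "
      f"({totals['male']} male, {totals['female']} female)")
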