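#!/usr/bin/env python
"""Comparative flux analysis: fold changes, cut-off, classes, pathways.

Compares the stress flux distribution against the control: log2 +
SD-normalization of positive fluxes, per-reaction fold changes, a
data-driven cut-off keeping significant changes below 30% of
reactions, up/down/unchanged/nonpositive classification, pathway and
carbon/nitrogen category summaries, and a KEGG Mapper color file.

Writes results/comparison/{comparison.tsv, pathways.tsv, kegg_colors.txt,
summary.json}.
"""

import argparse
import json
from pathlib import Path

from protflux import (
    FluxDistribution,
    compare,
    correlation,
    kegg_export,
    load_model,
    pathway_summary,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--fluxes", type=Path, default=Path("results/fluxes"))
    ap.add_argument("--out", type=Path, default=Path("results/comparison"))
    ap.add_argument("--max-proportion", type=float, default=0.30)
    args = ap.parse_args()

    model = load_model(args.data / "model.json")
    truth = json.loads((args.data / "truth.json").read_text())
    control = truth["control"]
    stress = next(c for c in truth["conditions"] if c != control)

    fd_ctrl = FluxDistribution.from_tsv(args.fluxes / f"flux_{control}.tsv")
    fd_str = FluxDistribution.from_tsv(args.fluxes / f"flux_{stress}.tsv")

    args.out.mkdir(parents=True, exist_ok=True)
    cmp = compare(fd_ctrl, fd_str, (control, stress), max_proportion=args.max_proportion)
    cmp.to_tsv(args.out / "comparison.tsv")
    counts = cmp.counts()
    print(
        f"{control} vs {stress}: cutoff {cmp.cutoff:.3f}; "
        f"{counts['up']} up, {counts['down']} down, "
        f"{counts['unchanged']} unchanged, {counts['nonpositive']} nonpositive"
    )

    summ = pathway_summary(cmp, model)
    summ.per_pathway.to_csv(args.out / "pathways.tsv", sep="\t")
    print(summ.per_pathway[["n_total", "n_up", "n_down", "pct_affected"]])

    annotation = {}
    for line in (args.data / "annotation.tsv").read_text().splitlines()[1:]:
        rid, kid = line.split("\t")
        annotation[rid] = kid
    n = kegg_export(cmp, annotation, args.out / "kegg_colors.txt")
    corr = correlation(fd_ctrl, fd_str, "pearson")
    print(f"{n} KEGG color lines; flux correlation r = {corr:.4f}")

    (args.out / "summary.json").write_text(
        json.dumps(
            {
                "condition_pair": [control, stress],
                "cutoff": cmp.cutoff,
                "counts": counts,
                "pearson_r": corr,
                "cn_ratio": summ.cn_ratio if summ.cn_ratio == summ.cn_ratio else None,
            },
            indent=1,
        )
    )


if __name__ == "__main__":
    main()
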