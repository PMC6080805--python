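"""Full primary x secondary cross-feeding enumeration for one organism.

Loops every primary carbon source of a genome-scale model against every
other primary-capable metabolite and keeps the pairs whose production
screen succeeds - the complete niche inventory of the metabolism.  On
iJO1366 this is an hour-scale batch (~32k LPs) yielding 83 distinct
secondary carbon sources and 9913 pairs; the pan-metabolic network (pass
its SBML with --model) yields 18959 pairs.

Usage:
    python examples/full_enumeration.py                      # bundled iJO1366
    python examples/full_enumeration.py --model path/to/model.xml
    python examples/full_enumeration.py --organism bsubtilis --model iYO844.xml
"""

import argparse

import crossfeed as cf
from crossfeed.carbon_niche import pairs_to_frame

MEDIA = {
    "ecoli": cf.ecoli_mineral_medium,
    "bsubtilis": cf.bsubtilis_mineral_medium,
    "scerevisiae": cf.scerevisiae_mineral_medium,
}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--model", help="SBML/JSON model (default: bundled iJO1366)")
    ap.add_argument("--organism", choices=sorted(MEDIA), default="ecoli",
                    help="mineral-medium preset")
    ap.add_argument("--dilution", type=float, default=0.2)
    ap.add_argument("--descriptors", action="store_true",
                    help="also compute p_max/alpha/cost per pair (slower)")
    ap.add_argument("--out", help="write the pair table as TSV")
    args = ap.parse_args()

    model = cf.load_model(args.model) if args.model else cf.load_bigg_model("iJO1366")
    medium = MEDIA[args.organism](model)

    pairs, summary = cf.enumerate_pairs(
        model, medium, dilution=args.dilution,
        with_descriptors=args.descriptors,
    )
    print(f"model: {model.cmodel.id or args.model}")
    for key, value in summary.items():
        print(f"{key}: {value}")
    if args.out:
        pairs_to_frame(pairs).to_csv(args.out, sep="\t", index=False)
        print(f"pair table written to {args.out}")


if __name__ == "__main__":
    main()
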