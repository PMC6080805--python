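"""MCMC sampling of random viable metabolic networks and their niche stats.

By default runs a desk-scale demonstration: a small random reaction
universe, 20 walks of 200 accepted reaction swaps each, followed by the
niche statistics (primary carbon sources per network, secondary sources on
the reference nutrient, cross-feeding pairs, and the production-fraction
ranking of secondaries).

With ``--full-scale --universe <pan_network.(xml|json)>`` the same entry
point runs the genome-scale protocol: 500 independent walks of 5000
accepted swaps over networks of 2583 reactions sampled from a pan-metabolic
universe (hours to days of CPU time).  Expected outcomes at that scale:
mean primary sources per network 32 +- 10, mean glucose secondaries
11 +- 5, a pooled union of ~84 secondary sources and ~15685 pairs, with
acetate and glycerol ranked about 19th and 13th by production fraction.
"""

import argparse

import numpy as np

import crossfeed as cf


def full_scale_config(seed: int) -> cf.WalkConfig:
    """The genome-scale sampling protocol (2583 reactions, 500 x 5000)."""
    return cf.WalkConfig(network_size=2583, burn_in=5000, n_walks=500, seed=seed)


def toy_config(universe: cf.Universe, seed: int) -> cf.WalkConfig:
    return cf.WalkConfig(
        network_size=universe.model.n_reactions - 3,
        burn_in=200, n_walks=20, seed=seed,
    )


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--full-scale", action="store_true")
    ap.add_argument("--universe", help="pan-network SBML/JSON for --full-scale")
    ap.add_argument("--out-dir", help="write bit-vector files here")
    args = ap.parse_args()

    if args.full_scale:
        if not args.universe:
            ap.error("--full-scale requires --universe <pan network file>")
        model = cf.load_model(args.universe)
        medium = cf.ecoli_mineral_medium(model).with_carbon("EX_glc__D_e", 10.0)
        protected = cf.essential_reactions(model, medium)
        universe = cf.Universe(model=model, medium=medium, protected=protected)
        config = full_scale_config(args.seed)
    else:
        universe = cf.make_toy_universe(cf.ToyUniverseSpec(seed=args.seed))
        universe = cf.Universe(
            model=universe.model, medium=universe.medium,
            protected=cf.essential_reactions(universe.model, universe.medium),
        )
        config = toy_config(universe, args.seed)

    nets = cf.run_walks(universe, config)
    stats = cf.sample_statistics(nets, universe)
    per = stats["per_network"]
    n_prim = [r["n_primaries"] for r in per]
    n_sec = [r["n_secondaries_on_reference"] for r in per]
    n_pairs = [r["n_pairs"] for r in per]

    print(f"{len(nets)} networks of {config.network_size} reactions, "
          f"{config.burn_in} accepted swaps each")
    print(f"primary sources per network:   {np.mean(n_prim):.1f} +- {np.std(n_prim):.1f}")
    print(f"secondaries on the reference:  {np.mean(n_sec):.1f} +- {np.std(n_sec):.1f}")
    print(f"pairs per network:             {np.mean(n_pairs):.1f} +- {np.std(n_pairs):.1f}")
    print(f"union: {len(stats['union_secondaries'])} secondaries, "
          f"{len(stats['union_pairs'])} pairs")
    print("top producible secondaries (fraction of networks producing them):")
    for rid, frac in stats["production_fraction_ranking"][:10]:
        print(f"  {rid:20s} {frac:.2f}")

    if args.out_dir:
        from pathlib import Path

        out = Path(args.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cf.write_reaction_index(out / "universe_index.tsv", universe.model)
        for net in nets:
            cf.write_bitvector(out / f"network_{net.walk_id:04d}.txt", net.bits)
        print(f"bit-vectors written to {out}/")


if __name__ == "__main__":
    main()
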