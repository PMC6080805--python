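"""Carbon-source niche screen on the bundled E. coli model iJO1366.

Counts the primary carbon sources (metabolites that sustain growth as the
sole carbon source of a mineral medium), the secondary carbon sources that
E. coli can excrete while growing on glucose, and the quantitative niche
descriptors of the experimentally known glucose-acetate pair: the maximal
acetate production rate p_max compatible with growth at the chemostat
dilution rate D = 0.2 h-1, acetate's biomass yield alpha = D/u*, and their
product alpha*p_max, which sets the consumer biomass a niche can carry.
"""

import crossfeed as cf

model = cf.load_bigg_model("iJO1366")
medium = cf.ecoli_mineral_medium(model)
D = 0.2

primaries = [r.exchange_id for r in cf.find_primary_sources(model, medium)]
print(f"primary carbon sources: {len(primaries)}")

secondaries = cf.enumerate_secondary(model, medium, "EX_glc__D_e",
                                     candidates=primaries)
print(f"secondary carbon sources on glucose: {len(secondaries)}")

p_max = cf.max_production_rate(model, medium, "EX_glc__D_e", "EX_ac_e",
                               dilution=D)
alpha, u_star = cf.biomass_yield(model, medium, "EX_ac_e", D)
print(f"acetate p_max at D={D}: {p_max:.1f} mmol gDW-1 h-1")
print(f"acetate yield alpha: {alpha:.4f} gDW/mmol (u* = {u_star:.2f})")
print(f"alpha * p_max: {alpha * p_max:.2f} h-1")
print()
print("Each of the", len(secondaries), "producible-and-growth-sustaining")
print("metabolites defines a cross-feeding niche on glucose; alpha*p_max is")
print("the growth potential it offers a consumer strain.")
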