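# Experiment configuration schema (all keys optional; defaults shown for a
# reduced smoke run — the full design uses the six sites, 100-season
# ensembles and 8 optimizer starts).
sites: [RR, LI]          # any of ED, LE, RR (UK), GO, LI, PU (NZ)
treatments: [CL_Base, CL_2050, IW_2050, IP_2050]
n_seasons: 30            # ensemble seasons per treatment
seed: 12345              # master seed; all stages derive sub-seeds from it
outdir: results/experiment
starts: 2                # EASA multi-start parents (one is cv. Claire)
offspring: 16            # candidates per optimization step
max_steps: 100
patience: 20             # steps without improvement before a start stops
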