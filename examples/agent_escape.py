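"""A mid-sized agent collective excavating its way out of the corral.

Runs the stochastic agent engine at the default preset (8 agents) and
prints the escape time and the pick/drop activity that produced it.
"""

from antcavate import AgentSimConfig, run_agent_sim

cfg = AgentSimConfig(n_agents=8, seed=5, store_trajectory=False)
res = run_agent_sim(cfg)

ts = cfg.crossing_time()
picks = (res.events.event == "pick").sum()
drops = (res.events.event == "drop").sum()
if res.censored:
    print(f"censored: no escape by Tstop = {cfg.Tstop:g} (T/ts = {res.T / ts:.1f})")
else:
    print(f"escape at T = {res.escape_time:.1f}  (T/ts = {res.T / ts:.2f})")
print(f"wall elements picked: {picks}, deposited in the interior: {drops}")
print("Agents deposit a communication field; where it exceeds the pick "
      "threshold they carry wall elements inward, and the growing gap "
      "becomes an escape channel. ts is the time to cross the arena.")
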