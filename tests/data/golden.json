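{
 "seed": 12345,
 "L": 8,
 "c": 0.125,
 "d": 0.25,
 "n_steps": 50,
 "site_obj": "bdd27bc7c5e95bea1588cf8e3a4a51bfcd22864d389c432f3ab66272a2f8ba47",
 "disp": "ca7f82f8c19ca97b41abb12a84aba7b4f5b15e1f2e3ec340f8fad14e24f163b9",
 "times": "f20efb5dad6fb714cc297c2b7f5984b195f597e161fbe29771495b50f4b4fcdb",
 "sites": "dd0db002b01a7f8fdcafb21b0401337d87d54adc7a10a8aafc4ba2f2192cfdd0",
 "e2e": "844b38847f7afa2bf26121e21b7bec236ae2f02f524412ae2da06d58ef153ea3",
 "decade_stats": "e15db56a641e7a00e232f79ac8de2372db0295eb92e91ce1efbb6e2ab25ad3ae"
}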