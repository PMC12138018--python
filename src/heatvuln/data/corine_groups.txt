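# CORINE Land Cover level-3 codes -> exposure group
# groups: artificial | non_vegetated_open | vegetated | water
# numerator of the exposed fraction = artificial + non_vegetated_open
111,artificial
112,artificial
121,artificial
122,artificial
123,artificial
124,artificial
131,artificial
132,artificial
133,artificial
141,artificial
142,artificial
211,vegetated
212,vegetated
213,vegetated
221,vegetated
222,vegetated
223,vegetated
231,vegetated
241,vegetated
242,vegetated
243,vegetated
244,vegetated
311,vegetated
312,vegetated
313,vegetated
321,vegetated
322,vegetated
323,vegetated
324,vegetated
331,non_vegetated_open
332,non_vegetated_open
333,non_vegetated_open
334,non_vegetated_open
335,non_vegetated_open
411,water
412,water
421,water
422,water
423,water
511,water
512,water
521,water
522,water
523,water
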