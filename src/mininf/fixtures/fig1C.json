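{
 "nodes": [
  "Z",
  "X",
  "Y",
  "W1",
  "W2",
  "U"
 ],
 "hidden": [
  "U"
 ],
 "edges": [
  [
   "W1",
   "Z"
  ],
  [
   "W2",
   "Z"
  ],
  [
   "W1",
   "U"
  ],
  [
   "W2",
   "U"
  ],
  [
   "U",
   "X"
  ],
  [
   "U",
   "Y"
  ],
  [
   "Z",
   "X"
  ],
  [
   "X",
   "Y"
  ]
 ],
 "arcs": []
}
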