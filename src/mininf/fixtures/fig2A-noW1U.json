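{
 "nodes": [
  "Z",
  "X",
  "Y1",
  "Y2",
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
   "W1",
   "Y1"
  ],
  [
   "W1",
   "Y2"
  ],
  [
   "U",
   "X"
  ],
  [
   "U",
   "Y1"
  ],
  [
   "Z",
   "X"
  ],
  [
   "X",
   "Y1"
  ],
  [
   "Z",
   "W2"
  ],
  [
   "Y2",
   "W2"
  ],
  [
   "W2",
   "Y1"
  ]
 ],
 "arcs": []
}
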