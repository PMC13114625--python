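{
 "nodes": [
  "Z",
  "X",
  "Y",
  "W",
  "U"
 ],
 "hidden": [
  "U"
 ],
 "edges": [
  [
   "W",
   "Z"
  ],
  [
   "W",
   "Y"
  ],
  [
   "Z",
   "X"
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
   "X",
   "Y"
  ]
 ],
 "arcs": []
}
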