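# State/territory -> CDC "Integrated Food Safety Centers of Excellence" region.
# The five regions are named after their hub states.  Region sizes: Colorado 10
# states; Minnesota 10 states; New York 12 states + DC; Tennessee 11 states +
# PR + VI; Washington 7 states + Guam.  The published assignment of member
# states is not part of this package's inputs, so this fixture is a synthetic
# geographically contiguous assignment consistent with those sizes, with each
# hub state in its own region.
Washington:
  [WA, OR, CA, NV, ID, AK, HI, GU]
Colorado:
  [CO, MT, WY, UT, AZ, NM, ND, SD, NE, KS]
Minnesota:
  [MN, WI, MI, IL, IN, OH, IA, MO, OK, TX]
New York:
  [NY, NJ, PA, CT, RI, MA, VT, NH, ME, DE, MD, VA, DC]
Tennessee:
  [TN, KY, WV, NC, SC, GA, FL, AL, MS, AR, LA, PR, VI]
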