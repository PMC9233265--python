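{
  "templates": {
    "LT40": [
      "Hi, {name}! You did around {steps} steps so far and reached {pct}% of your goal for today. There is still plenty of day left - a short walk now would be a great start. Interesting fact: {benefit}",
      "Hey {name}, {steps} steps so far puts you at {pct}% of today's goal. Every journey starts with a first step - how about a stroll around the block? Remember: {benefit}",
      "Hi {name}! With {steps} steps you are at {pct}% of your goal. No worries - evenings are perfect for catching up. Did you know? {benefit}",
      "Hello {name}, you have {steps} steps ({pct}% of your goal). A quick errand on foot could turn this day around. Fun fact: {benefit}",
      "Hey {name}! {steps} steps and {pct}% of the goal so far. Put on your favourite song and move a little - it adds up fast. Also: {benefit}",
      "Hi {name}, {steps} steps so far - {pct}% of today's target. Even ten active minutes now will make a difference. Keep in mind: {benefit}"
    ],
    "GE40": [
      "Hi, {name}! You did around {steps} steps so far and reached {pct}% of your goal for today - a solid base, keep building on it! Interesting fact: {benefit}",
      "Hey {name}, {steps} steps already - that is {pct}% of your goal. Nice momentum, a walk after dinner would push it further. Remember: {benefit}",
      "Hello {name}! {steps} steps and {pct}% of the way there. You are warming up nicely - keep it rolling. Did you know? {benefit}",
      "Hi {name}, you are at {pct}% with {steps} steps. Almost halfway - a small effort tonight pays off. Fun fact: {benefit}",
      "Hey {name}! {steps} steps so far ({pct}% of the goal). Good pace - how about stretching your legs for a bit? Also: {benefit}"
    ],
    "GE60": [
      "Hi, {name}! You did around {steps} steps so far and reached {pct}% of your goal for today - well over half, nicely done! Interesting fact: {benefit}",
      "Hey {name}, {steps} steps - {pct}% of today's goal. You are clearly on track; one more walk seals it. Remember: {benefit}",
      "Hello {name}! With {steps} steps you hit {pct}% of your goal. Great going - the finish line is in sight. Did you know? {benefit}",
      "Hi {name}, {pct}% done with {steps} steps. Strong day so far - keep that energy up! Fun fact: {benefit}",
      "Hey {name}! {steps} steps so far puts you at {pct}%. Impressive - a short evening stroll gets you home. Also: {benefit}"
    ],
    "GE80": [
      "Hi, {name}! You did around {steps} steps so far and reached {pct}% of your goal for today - good job, can you do even better? Interesting fact: {benefit}",
      "Hey {name}, {steps} steps - {pct}% of the goal! So close you can almost touch it. Remember: {benefit}",
      "Hello {name}! {steps} steps and {pct}% reached. One last push and the goal is yours. Did you know? {benefit}",
      "Hi {name}, you are at {pct}% with {steps} steps - excellent work today. A few more minutes on your feet will do it. Fun fact: {benefit}",
      "Hey {name}! {pct}% of your goal with {steps} steps. Outstanding - finish strong! Also: {benefit}"
    ],
    "GE100": [
      "Hi, {name}! You did around {steps} steps so far and reached {pct}% of your goal for today - goal smashed, congratulations! Interesting fact: {benefit}",
      "Hey {name}, {steps} steps - {pct}% of your goal. You beat your target today, amazing! Remember: {benefit}",
      "Hello {name}! {steps} steps and {pct}% - over the top! Celebrate with a victory lap. Did you know? {benefit}",
      "Hi {name}, {pct}% reached with {steps} steps. Fantastic - every extra step is a bonus for your health. Fun fact: {benefit}",
      "Hey {name}! {steps} steps today, {pct}% of the goal. Champion effort - keep the streak alive tomorrow! Also: {benefit}"
    ]
  },
  "benefits": [
    "physical activity benefits improved concentration, so if you are active, you may get better study results!",
    "regular physical activity strengthens your heart and lungs.",
    "being active during the day helps you sleep better at night.",
    "active breaks reduce stress and lift your mood.",
    "walking regularly strengthens bones and muscles while they are still growing.",
    "active adolescents usually stay active as adults - habits built now last a lifetime.",
    "moving more during the day improves your energy levels and reduces tiredness."
  ]
}
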