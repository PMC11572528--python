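# Emergency-resilience evaluation scale for grassroots medical workers:
# three-level weighted indicator hierarchy (3 first-level, 13 second-level,
# 46 third-level indicators) with AHM-derived local weights.
name: grassroots-medical-worker-emergency-resilience
rating_scale: {min: 1, max: 5}
indicators:
- id: x1
  text: Professional quality
  weight: 0.346
  children:
  - id: x11
    text: Communication skills
    weight: 0.465
    children:
    - {id: x111, weight: 0.200, text: "I can communicate well with the residents in dialect (for example in Guangdong province: Cantonese)."}
    - {id: x112, weight: 0.396, text: "I can assist the unit in the documentation and publicity work (such as the writing of the official account of the unit, propaganda and education documents, etc.)."}
    - {id: x113, weight: 0.404, text: "At work, I can express academic ideas accurately, scientifically and rigorously, and exchange research results."}
  - id: x12
    text: Social mobilization
    weight: 0.035
    children:
    - {id: x121, weight: 0.286, text: "I am willing to have the initiative to understand the public health situation at the global, national, regional and community levels."}
    - {id: x122, weight: 0.377, text: "I would like to find community partners to carry out actions to promote the health of the residents."}
    - {id: x123, weight: 0.337, text: "I will pay close attention to current public health policies and seek opportunities to participate in activities that improve them."}
  - id: x13
    text: Teamwork
    weight: 0.185
    children:
    - {id: x131, weight: 0.275, text: "When performing tasks, I prefer team tasks where I can work with others."}
    - {id: x132, weight: 0.725, text: "When carrying out emergency rescue tasks with the team, I will actively learn task-related information and actively share with members."}
  - id: x14
    text: Organization and coordination skills
    weight: 0.315
    children:
    - {id: x141, weight: 0.512, text: "During public health operations, I can quickly adjust myself to align my work status with the organization's activities."}
    - {id: x142, weight: 0.488, text: "I can encourage others to participate in action so as to promote internal collaboration."}
- id: x2
  text: Psychological capital
  weight: 0.614
  children:
  - id: x21
    text: Optimism
    weight: 0.039
    children:
    - {id: x211, weight: 0.275, text: "I always see the bright side of things in my work."}
    - {id: x212, weight: 0.259, text: "I am optimistic about what will happen to my job in the future."}
    - {id: x213, weight: 0.466, text: "In the face of public health events such as the COVID-19 pandemic, I always believe that 'there is a light at the end of the tunnel, do not be pessimistic.'"}
  - id: x22
    text: Toughness
    weight: 0.198
    children:
    - {id: x221, weight: 0.220, text: "I believe I can work through any challenge I have at work."}
    - {id: x222, weight: 0.254, text: "I can do it on my own if I have to do hard work alone."}
    - {id: x223, weight: 0.063, text: "I usually take stress at work in stride."}
    - {id: x224, weight: 0.230, text: "Even in the face of public health outbreaks, I am able to survive difficult times at work."}
    - {id: x225, weight: 0.234, text: "In my current job, I feel like I can juggle many things at once."}
  - id: x23
    text: Hope
    weight: 0.318
    children:
    - {id: x231, weight: 0.313, text: "If I find myself stuck at work, I can think of many ways to get out of it."}
    - {id: x232, weight: 0.097, text: "At present, I am full of energy to complete my work goals."}
    - {id: x233, weight: 0.137, text: "There are many solutions to any problem."}
    - {id: x234, weight: 0.100, text: "At the moment I am quite satisfied with what I have achieved in my work."}
    - {id: x235, weight: 0.192, text: "I can think of a number of ways to achieve my current workday goals."}
    - {id: x236, weight: 0.161, text: "At the moment, I am achieving the work goals I set for myself."}
  - id: x24
    text: Effectiveness
    weight: 0.445
    children:
    - {id: x241, weight: 0.163, text: "I believe I can analyze long-term problems and find solutions."}
    - {id: x242, weight: 0.065, text: "In meetings, I am confident in stating things that are within the scope of my job."}
    - {id: x243, weight: 0.184, text: "I think I can improve the general well-being in the community which I work for."}
    - {id: x244, weight: 0.137, text: "Within the scope of my job, I believe I can help set goals/objectives."}
    - {id: x245, weight: 0.177, text: "I believe in my ability to connect with people outside my working department to solve some related problems."}
    - {id: x246, weight: 0.273, text: "If I were in the scene of a public health emergency, I believe I would be able to calmly analyze the situation and work on the front lines as soon as possible."}
- id: x3
  text: Emergency attitude
  weight: 0.040
  children:
  - id: x31
    text: Disaster relief expectation
    weight: 0.277
    children:
    - {id: x311, weight: 0.277, text: "If I have chance, I am willing to participate in the rescue work of public health emergencies."}
    - {id: x312, weight: 0.218, text: "If I have chance, I am willing to assist in the disinfection of the epidemic area."}
    - {id: x313, weight: 0.235, text: "During the public health emergency, I would be willing to receive psychological training to provide the psychological care and interventions that patients or community residents need."}
    - {id: x314, weight: 0.269, text: "As a grass-roots medical worker, if I realize that there is a crisis of public health events such as infectious diseases, I will do all in my power to send a protective warning to the outside world."}
  - id: x32
    text: Trained attitude
    weight: 0.191
    children:
    - {id: x321, weight: 0.197, text: "I am willing to learn more about public health emergencies."}
    - {id: x322, weight: 0.259, text: "It is necessary to carry out public health emergency related courses and training."}
    - {id: x323, weight: 0.246, text: "It is necessary to carry out emergency drills for public health emergencies."}
    - {id: x324, weight: 0.297, text: "It is important to master the basic knowledge of public health emergencies."}
  - id: x33
    text: Mental reaction
    weight: 0.040
    children:
    - {id: x331, weight: 0.533, text: "I am terrified of a public health emergency."}
    - {id: x332, weight: 0.467, text: "Performing tasks related to public health emergencies such as daily epidemic prevention will make me feel stressed."}
  - id: x34
    text: Awareness of prevention
    weight: 0.363
    children:
    - {id: x341, weight: 0.256, text: "It is necessary to equip the household with emergency medicine kit (containing disinfectant, mask, anti-inflammatory drugs, anti-allergic drugs and other items), fire extinguisher and other basic emergency materials."}
    - {id: x342, weight: 0.336, text: "I am willing to assist community residents to carry out preventive vaccination and preventive medication."}
    - {id: x343, weight: 0.409, text: "I am willing to actively communicate with community residents and carry out health education on public health emergencies."}
  - id: x35
    text: Self-evaluation
    weight: 0.129
    children:
    - {id: x351, weight: 0.356, text: "I am familiar with public health emergencies."}
    - {id: x352, weight: 0.299, text: "I will pay attention to the epidemic situation of local infectious diseases actively."}
    - {id: x353, weight: 0.345, text: "I will follow the World Health Organization's reports on various public health emergencies."}
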